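"""A seeded self-organising map for the hierarchical-SOM base clusterer.

The map is a rectangular prototype grid fitted to the data; items are then
clustered by Ward-linking the trained codebook and labelling each item with
its best-matching unit's cluster (see :mod:`gpclusters.base_clusterers`).

Training is batch-style: every epoch all samples are assigned to their
best-matching unit, and each prototype moves toward the neighbourhood-
weighted mean of the assigned samples. The Gaussian neighbourhood radius
and a damping (learning-rate) factor both decay linearly over epochs, so
the map orders globally early and converges locally late. Batch updates
make the fit independent of sample order and fast to vectorise.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


class SelfOrganisingMap:
    """Batch-trained SOM on a rectangular grid.

    Parameters
    ----------
    grid : (rows, cols), default (8, 8)
    epochs : training epochs, default 500
    sigma_start, sigma_end : Gaussian neighbourhood radius (grid units),
        decayed linearly; defaults half the larger grid side down to 0.5.
    lr_start, lr_end : damping factor on each batch update, decayed linearly.
    seed : seeds codebook initialisation (random data points with jitter).
    """

    def __init__(
        self,
        grid: tuple[int, int] = (8, 8),
        epochs: int = 500,
        sigma_start: float | None = None,
        sigma_end: float = 0.5,
        lr_start: float = 0.5,
        lr_end: float = 0.02,
        seed: int = 0,
    ):
        self.grid = grid
        self.epochs = epochs
        self.sigma_start = sigma_start if sigma_start is not None else max(grid) / 2.0
        self.sigma_end = sigma_end
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.seed = seed
        self.codebook_: np.ndarray | None = None
        rows, cols = grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        units = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        # squared grid distances between units, fixed for the lifetime of the map
        self._grid_d2 = cdist(units, units, "sqeuclidean")

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    def fit(self, X: np.ndarray) -> "SelfOrganisingMap":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        idx = rng.integers(0, n, size=self.n_units)
        scale = X.std(axis=0, ddof=0)
        W = X[idx] + rng.normal(0.0, 1.0, size=(self.n_units, d)) * 0.05 * scale
        for epoch in range(self.epochs):
            t = epoch / max(self.epochs - 1, 1)
            sigma = self.sigma_start + t * (self.sigma_end - self.sigma_start)
            lr = self.lr_start + t * (self.lr_end - self.lr_start)
            bmu = np.argmin(cdist(X, W, "sqeuclidean"), axis=1)
            sums = np.zeros((self.n_units, d))
            np.add.at(sums, bmu, X)
            counts = np.bincount(bmu, minlength=self.n_units).astype(float)
            H = np.exp(-self._grid_d2 / (2.0 * sigma * sigma))
            numer = H @ sums
            denom = H @ counts
            mask = denom > 0
            W[mask] += lr * (numer[mask] / denom[mask, None] - W[mask])
        self.codebook_ = W
        return self

    def best_matching_units(self, X: np.ndarray) -> np.ndarray:
        if self.codebook_ is None:
            raise RuntimeError("SOM not fitted")
        return np.argmin(cdist(np.asarray(X, float), self.codebook_, "sqeuclidean"), axis=1)
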