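"""The five base clustering methods used inside the ensemble.

Each method partitions the rows of a scaled measure matrix into ``k``
groups, deterministically given ``(method, data, seed)``:

- ``kmeans_lloyd``: Lloyd's k-means from seeded k-means++ starts, best of
  10 restarts by within-cluster sum of squares (scikit-learn).
- ``hierarchical_ward``: agglomerative merges minimising the Ward variance
  increase on Euclidean distances, cut at ``k`` (scikit-learn).
- ``hsom``: a seeded self-organising map (8x8 grid by default) whose
  trained codebook is Ward-clustered into ``k``; items take their
  best-matching unit's cluster.
- ``pam``: partitioning around medoids, BUILD + SWAP on Euclidean
  distances.
- ``gmm_bic``: Gaussian mixture fitted by EM at fixed ``k`` over several
  covariance families, the best BIC wins; items are assigned to their
  maximum-responsibility component. Singular fits fall back to the
  diagonal family.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .pam import pam_cluster
from .som import SelfOrganisingMap

BASE_METHODS = ("kmeans_lloyd", "hierarchical_ward", "hsom", "pam", "gmm_bic")

DEFAULT_GMM_COVARIANCES = ("full", "tied", "diag", "spherical")
DEFAULT_SOM_PARAMS = {"grid": (8, 8), "epochs": 500}


def _kmeans(X, k, seed):
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, algorithm="lloyd", random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return km.fit_predict(X)


def _ward(X, k, seed):
    return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)


def _hsom(X, k, seed, som_params=None):
    params = dict(DEFAULT_SOM_PARAMS)
    if som_params:
        params.update(som_params)
    som = SelfOrganisingMap(seed=seed, **params).fit(X)
    unit_labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
        som.codebook_
    )
    return unit_labels[som.best_matching_units(X)]


def _gmm_bic(X, k, seed, covariances=DEFAULT_GMM_COVARIANCES):
    best_bic, best_labels = np.inf, None
    for cov in covariances:
        labels, bic = _fit_gmm(X, k, seed, cov)
        if labels is not None and bic < best_bic:
            best_bic, best_labels = bic, labels
    if best_labels is None:
        labels, _ = _fit_gmm(X, k, seed, "diag", reg=1e-3)
        if labels is None:
            raise RuntimeError("GMM failed for every covariance family")
        best_labels = labels
    return best_labels


def _fit_gmm(X, k, seed, cov, reg=1e-6):
    gm = GaussianMixture(
        n_components=k,
        covariance_type=cov,
        random_state=seed,
        n_init=1,
        reg_covar=reg,
        max_iter=200,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = gm.fit_predict(X)
        return labels, gm.bic(X)
    except (ValueError, np.linalg.LinAlgError):
        return None, np.inf


def run_base_clusterer(
    method: str,
    X: np.ndarray,
    k: int,
    seed: int,
    som_params: dict | None = None,
    gmm_covariances=DEFAULT_GMM_COVARIANCES,
) -> np.ndarray:
    """Partition the rows of ``X`` into ``k`` clusters with one base method.

    Returns integer labels in [0, k). Deterministic given
    ``(method, X, seed)``. ``k`` must be smaller than the number of rows.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    if not 2 <= k < len(X):
        raise ValueError(f"need 2 <= k < n_items, got k={k}, n={len(X)}")
    if method == "kmeans_lloyd":
        labels = _kmeans(X, k, seed)
    elif method == "hierarchical_ward":
        labels = _ward(X, k, seed)
    elif method == "hsom":
        labels = _hsom(X, k, seed, som_params)
    elif method == "pam":
        labels = pam_cluster(X, k, seed)
    elif method == "gmm_bic":
        labels = _gmm_bic(X, k, seed, gmm_covariances)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {BASE_METHODS}")
    return np.asarray(labels, dtype=int)


def is_degenerate(labels: np.ndarray, k: int) -> bool:
    """True when some cluster received no items (or the data collapsed)."""
    return len(np.unique(labels)) < k
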