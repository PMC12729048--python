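"""Partitioning around medoids (PAM): BUILD initialisation plus SWAP descent.

Classic k-medoids on Euclidean distances. BUILD greedily seeds the medoid
set (first the item minimising total distance, then the item giving the
largest cost reduction); SWAP repeatedly applies the single
(medoid, non-medoid) exchange that most reduces total cost until no
exchange improves it. Both phases are deterministic given the data —
ensemble diversity comes from the subsample each run sees, not from the
seed, which only breaks exact ties.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist


def pam_cluster(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 100) -> np.ndarray:
    """Cluster rows of ``X`` into ``k`` groups around medoids.

    Returns integer labels in [0, k). Labels are indexed by medoid order
    (medoids sorted by item index) so the labelling is deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n_items, got k={k}, n={n}")
    D = squareform(pdist(X))
    rng = np.random.default_rng(seed)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        # gain of adding candidate j: sum over points of max(0, nearest - d(i, j))
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = np.flatnonzero(gains == gains.max())
        medoids.append(int(rng.choice(best)) if len(best) > 1 else int(best[0]))

    # SWAP (steepest descent)
    medoids = sorted(medoids)
    for _ in range(max_iter):
        Dm = D[:, medoids]
        order = np.argsort(Dm, axis=1)
        nearest = Dm[np.arange(n), order[:, 0]]
        second = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        which = order[:, 0]
        cost = nearest.sum()
        best_delta, best_swap = 1e-10, None  # require strict improvement
        for mi in range(k):
            # removing medoid mi: points whose nearest was mi fall back to `second`
            fallback = np.where(which == mi, second, nearest)
            # candidate h replaces it: each point takes min(fallback, d(., h))
            cand_costs = np.minimum(D, fallback[:, None]).sum(axis=0)
            cand_costs[medoids] = np.inf
            h = int(np.argmin(cand_costs))
            delta = cost - cand_costs[h]
            if delta > best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels.astype(int)
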