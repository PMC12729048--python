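"""Ensemble consensus clustering with subsampling and majority voting.

The procedure: each of several base clustering methods is run repeatedly,
each repetition on a fresh random subsample of 80% of practices. The runs
are label-aligned to a reference run (the one most similar, by mean
adjusted Rand index, to all the others), and each practice's final cluster
is the majority vote over the aligned runs that sampled it. Practices a
run never sampled, or with tied votes, are assigned to the nearest
consensus centroid. Stability is summarised by the mean pairwise adjusted
Rand index over all run pairs, each computed on the items the pair shares.

The model/results pair :class:`ConsensusClustering` / :class:`ConsensusResult`
wraps the module-level operations (`build_ensemble`, `relabel_runs`,
`majority_vote`, ...), which remain usable on their own.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .base_clusterers import (
    BASE_METHODS,
    DEFAULT_GMM_COVARIANCES,
    is_degenerate,
    run_base_clusterer,
)


# ---------------------------------------------------------------------------
# Adjusted Rand index
# ---------------------------------------------------------------------------

def contingency_table(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Overlap counts n_ij between the classes of two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same items")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) with
    E = [sum_i C(a_i,2) * sum_j C(b_j,2)] / C(n,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2. When M = E (e.g. both
    partitions trivial) the index is 1 for identical partitions, else 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 common items")
    table = contingency_table(a, b)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # partitions identical up to relabelling iff the table is
        # permutation-like (at most one non-zero per row and column)
        perm_like = ((table > 0).sum(axis=0) <= 1).all() and (
            (table > 0).sum(axis=1) <= 1
        ).all()
        return 1.0 if perm_like else 0.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# Ensemble construction
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    """Protocol for the ensemble: which methods, how many repetitions,
    the subsample fraction, and the number of clusters."""

    k: int = 2
    methods: tuple[str, ...] = BASE_METHODS
    reps_per_method: int = 100
    subsample_fraction: float = 0.8
    master_seed: int = 0
    som_params: dict = field(default_factory=dict)
    gmm_covariances: tuple[str, ...] = DEFAULT_GMM_COVARIANCES

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.reps_per_method < 1:
            raise ValueError("reps_per_method must be >= 1")
        unknown = set(self.methods) - set(BASE_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


@dataclass
class ClusterRun:
    """One base-clusterer result on one subsample."""

    method: str
    seed: int
    item_indices: np.ndarray  # sorted indices into the full matrix
    labels: np.ndarray  # one label in [0, k) per sampled item
    degenerate: bool = False

    def full_labels(self, n_items: int) -> np.ndarray:
        """Labels on the full index, -1 where the run did not sample."""
        full = np.full(n_items, -1, dtype=int)
        full[self.item_indices] = self.labels
        return full


def run_seed(master_seed: int, method: str, rep: int) -> int:
    """Stable per-run seed: SHA-256 of ``"master:method:rep"``, < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{method}:{rep}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_ensemble(X: np.ndarray, config: EnsembleConfig) -> list[ClusterRun]:
    """Run every method x repetition on seeded 80% subsamples.

    Each run draws ``ceil(fraction * n)`` items without replacement with a
    seed derived deterministically from the master seed, so the whole
    ensemble is reproducible bit-for-bit.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    m = math.ceil(config.subsample_fraction * n)
    runs: list[ClusterRun] = []
    for method in config.methods:
        for rep in range(config.reps_per_method):
            seed = run_seed(config.master_seed, method, rep)
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(n, size=m, replace=False))
            labels = run_base_clusterer(
                method,
                X[idx],
                config.k,
                seed,
                som_params=config.som_params or None,
                gmm_covariances=config.gmm_covariances,
            )
            runs.append(
                ClusterRun(
                    method=method,
                    seed=seed,
                    item_indices=idx,
                    labels=labels,
                    degenerate=is_degenerate(labels, config.k),
                )
            )
    return runs


# ---------------------------------------------------------------------------
# Pairwise ARI, alignment, voting
# ---------------------------------------------------------------------------

def _pairwise_ari_matrix(runs: list[ClusterRun], n_items: int) -> np.ndarray:
    """Symmetric matrix of pairwise ARIs on each pair's common items
    (NaN where a pair shares fewer than 2 items)."""
    L = np.stack([r.full_labels(n_items) for r in runs])
    n_runs = len(runs)
    out = np.full((n_runs, n_runs), np.nan)
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            common = (L[i] >= 0) & (L[j] >= 0)
            if common.sum() < 2:
                continue
            out[i, j] = out[j, i] = adjusted_rand(L[i][common], L[j][common])
    return out


def mean_pairwise_ari(runs: list[ClusterRun], n_items: int | None = None) -> float:
    """Unweighted mean ARI over all unordered run pairs (common items).

    Pairs sharing fewer than 2 items are skipped; if every pair is skipped
    this is an error.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    if n_items is None:
        n_items = max(int(r.item_indices.max()) for r in runs) + 1
    matrix = _pairwise_ari_matrix(runs, n_items)
    vals = matrix[np.triu_indices(len(runs), k=1)]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no run pair shares at least 2 items")
    return float(vals.mean())


def best_label_mapping(labels_ref: np.ndarray, labels_other: np.ndarray, k: int) -> np.ndarray:
    """Permutation ``perm`` maximising overlap, so ``perm[labels_other]``
    best matches ``labels_ref`` (optimal assignment on the k x k table)."""
    table = np.zeros((k, k), dtype=np.int64)
    np.add.at(table, (labels_other, labels_ref), 1)
    rows, cols = linear_sum_assignment(-table)
    perm = np.arange(k)
    perm[rows] = cols
    return perm


def relabel_runs(
    runs: list[ClusterRun], n_items: int, k: int
) -> tuple[list[ClusterRun], int, np.ndarray]:
    """Align every run's labels to a common reference.

    The reference is the run with the highest mean ARI to all others;
    each other run is permuted by the optimal k x k matching on the items
    it shares with the reference. Returns (aligned runs, reference index,
    pairwise ARI matrix) — the matrix is reusable since ARI is invariant
    to the relabelling.
    """
    if not runs:
        raise ValueError("need at least 1 run")
    if len(runs) == 1:
        return list(runs), 0, np.full((1, 1), np.nan)
    matrix = _pairwise_ari_matrix(runs, n_items)
    mean_to_others = np.nanmean(matrix, axis=1)
    ref = int(np.nanargmax(mean_to_others))
    ref_full = runs[ref].full_labels(n_items)
    aligned = []
    for i, run in enumerate(runs):
        if i == ref:
            aligned.append(replace(run))
            continue
        full = run.full_labels(n_items)
        common = (full >= 0) & (ref_full >= 0)
        if common.sum() == 0:
            aligned.append(replace(run))
            continue
        perm = best_label_mapping(ref_full[common], full[common], k)
        aligned.append(replace(run, labels=perm[run.labels]))
    return aligned, ref, matrix


def majority_vote(
    aligned_runs: list[ClusterRun],
    n_items: int,
    k: int,
    X: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-item majority vote over aligned runs.

    Returns ``(labels, vote_share, n_votes, n_fallback)``. Ties and items
    no run sampled fall back to nearest-centroid assignment
    (:func:`assign_unvoted`) when ``X`` is given; without ``X`` ties take
    the lower label index. ``vote_share`` is the winning label's fraction
    of the item's votes (NaN for zero-vote items).
    """
    votes = np.zeros((n_items, k), dtype=int)
    for run in aligned_runs:
        np.add.at(votes, (run.item_indices, run.labels), 1)
    n_votes = votes.sum(axis=1)
    winner = votes.argmax(axis=1)
    top = votes.max(axis=1)
    tied = (votes == top[:, None]).sum(axis=1) > 1
    unresolved = tied | (n_votes == 0)
    labels = winner.copy()
    n_fallback = int(unresolved.sum())
    if n_fallback and X is not None:
        decided = ~unresolved
        if decided.sum() == 0 or len(np.unique(labels[decided])) < k:
            raise ValueError("cannot form centroids: a consensus cluster is empty")
        centroids = consensus_centroids(np.asarray(X, float)[decided], labels[decided], k)
        for i in np.flatnonzero(unresolved):
            labels[i] = assign_unvoted(np.asarray(X, float)[i], centroids)
    with np.errstate(invalid="ignore", divide="ignore"):
        vote_share = np.where(n_votes > 0, votes[np.arange(n_items), labels] / n_votes, np.nan)
    return labels, vote_share, n_votes, n_fallback


def consensus_centroids(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Euclidean mean of the items assigned to each consensus cluster."""
    cents = np.empty((k, X.shape[1]))
    for c in range(k):
        members = labels == c
        if not members.any():
            raise ValueError(f"consensus cluster {c} is empty")
        cents[c] = X[members].mean(axis=0)
    return cents


def assign_unvoted(x: np.ndarray, centroids: np.ndarray) -> int:
    """Label of the nearest centroid; distance ties take the lower index."""
    d = np.linalg.norm(centroids - x, axis=1)
    return int(np.argmin(d))  # argmin returns the first (lowest) index on ties


def co_association(runs: list[ClusterRun], n_items: int) -> np.ndarray:
    """Diagnostic co-association matrix: for each item pair, the fraction
    of runs sampling both that put them in the same cluster."""
    same = np.zeros((n_items, n_items))
    both = np.zeros((n_items, n_items))
    for run in runs:
        idx = run.item_indices
        eq = (run.labels[:, None] == run.labels[None, :]).astype(float)
        same[np.ix_(idx, idx)] += eq
        both[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(both > 0, same / both, np.nan)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ConsensusClustering:
    """Consensus clustering model over a scaled measure matrix.

    Parameters mirror :class:`EnsembleConfig`; ``data`` is an
    (items x features) array or DataFrame (index = practice ids). ``fit``
    runs the full ensemble -> align -> vote procedure and returns a
    :class:`ConsensusResult`.
    """

    def __init__(
        self,
        data,
        k: int = 2,
        methods: tuple[str, ...] = BASE_METHODS,
        reps_per_method: int = 100,
        subsample_fraction: float = 0.8,
        som_params: dict | None = None,
        gmm_covariances: tuple[str, ...] = DEFAULT_GMM_COVARIANCES,
    ):
        if isinstance(data, pd.DataFrame):
            self.item_ids = list(data.index)
            self.X = data.to_numpy(dtype=float)
        else:
            self.X = np.asarray(data, dtype=float)
            self.item_ids = list(range(len(self.X)))
        if not np.isfinite(self.X).all():
            raise ValueError("data must be finite")
        self.k = k
        self.methods = tuple(methods)
        self.reps_per_method = reps_per_method
        self.subsample_fraction = subsample_fraction
        self.som_params = som_params or {}
        self.gmm_covariances = tuple(gmm_covariances)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns: list[str] | None = None, **kwargs):
        if columns is not None:
            df = df[columns]
        return cls(df, **kwargs)

    def config(self, master_seed: int = 0) -> EnsembleConfig:
        return EnsembleConfig(
            k=self.k,
            methods=self.methods,
            reps_per_method=self.reps_per_method,
            subsample_fraction=self.subsample_fraction,
            master_seed=master_seed,
            som_params=self.som_params,
            gmm_covariances=self.gmm_covariances,
        )

    def fit(self, master_seed: int = 0) -> "ConsensusResult":
        config = self.config(master_seed)
        runs = build_ensemble(self.X, config)
        n = len(self.X)
        aligned, ref, matrix = relabel_runs(runs, n, self.k)
        labels, vote_share, n_votes, n_fallback = majority_vote(
            aligned, n, self.k, X=self.X
        )
        tri = matrix[np.triu_indices(len(runs), k=1)]
        tri = tri[~np.isnan(tri)]
        per_method = {}
        for method in config.methods:
            sel = np.array([r.method == method for r in runs])
            sub = matrix[np.ix_(sel, sel)]
            vals = sub[np.triu_indices(sel.sum(), k=1)]
            vals = vals[~np.isnan(vals)]
            per_method[method] = float(vals.mean()) if len(vals) else float("nan")
        return ConsensusResult(
            model=self,
            config=config,
            runs=aligned,
            reference_run=ref,
            labels=np.asarray(labels),
            vote_share=np.asarray(vote_share),
            n_votes=np.asarray(n_votes),
            n_fallback=n_fallback,
            mean_pairwise_ari=float(tri.mean()) if len(tri) else float("nan"),
            per_method_ari=per_method,
        )


@dataclass
class ConsensusResult:
    """Fitted consensus partition with vote diagnostics.

    ``labels`` are the final per-item clusters, ``vote_share`` the winning
    label's fraction of each item's votes, ``mean_pairwise_ari`` the
    stability of the underlying ensemble.
    """

    model: ConsensusClustering
    config: EnsembleConfig
    runs: list[ClusterRun]
    reference_run: int
    labels: np.ndarray
    vote_share: np.ndarray
    n_votes: np.ndarray
    n_fallback: int
    mean_pairwise_ari: float
    per_method_ari: dict[str, float]

    @property
    def item_ids(self) -> list:
        return self.model.item_ids

    def cluster_sizes(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in range(self.config.k)}

    def centroids(self) -> np.ndarray:
        return consensus_centroids(self.model.X, self.labels, self.config.k)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Assign new scaled vectors to the nearest consensus centroid."""
        cents = self.centroids()
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return np.array([assign_unvoted(x, cents) for x in X_new])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "practice_id": self.item_ids,
                "cluster": self.labels,
                "vote_share": self.vote_share,
                "n_votes": self.n_votes,
            }
        )

    def co_association(self) -> np.ndarray:
        return co_association(self.runs, len(self.model.X))

    def diagnostics(self) -> dict:
        return {
            "mean_pairwise_ari": self.mean_pairwise_ari,
            "per_method_ari": self.per_method_ari,
            "reference_run": self.reference_run,
            "n_runs": len(self.runs),
            "n_degenerate_runs": int(sum(r.degenerate for r in self.runs)),
            "n_fallback_items": self.n_fallback,
            "cluster_sizes": self.cluster_sizes(),
            "config": {
                "k": self.config.k,
                "methods": list(self.config.methods),
                "reps_per_method": self.config.reps_per_method,
                "subsample_fraction": self.config.subsample_fraction,
                "master_seed": self.config.master_seed,
            },
        }

    def summary(self) -> str:
        lines = [
            "Consensus clustering results",
            "=" * 44,
            f"items                {len(self.labels)}",
            f"clusters (k)         {self.config.k}",
            f"methods              {', '.join(self.config.methods)}",
            f"runs                 {len(self.runs)} "
            f"({self.config.reps_per_method} reps x {len(self.config.methods)} methods)",
            f"subsample fraction   {self.config.subsample_fraction:.2f}",
            f"mean pairwise ARI    {self.mean_pairwise_ari:.4f}",
            "-" * 44,
        ]
        for c, n in self.cluster_sizes().items():
            share = n / len(self.labels)
            mean_vs = np.nanmean(self.vote_share[self.labels == c])
            lines.append(
                f"cluster {c}: n={n} ({100 * share:.1f}%), "
                f"mean vote share {mean_vs:.3f}"
            )
        lines.append("-" * 44)
        for method, ari in self.per_method_ari.items():
            lines.append(f"within-method ARI {method:<18} {ari:.4f}")
        return "\n".join(lines)
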