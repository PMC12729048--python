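"""Adjusted Rand index, base clusterers, ensemble bookkeeping, alignment
and majority voting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from gpclusters.base_clusterers import BASE_METHODS, run_base_clusterer
from gpclusters.ensemble import (
    ClusterRun,
    ConsensusClustering,
    EnsembleConfig,
    adjusted_rand,
    build_ensemble,
    majority_vote,
    mean_pairwise_ari,
    relabel_runs,
    run_seed,
)


# ---------------------------------------------------------------------------
# ARI
# ---------------------------------------------------------------------------

def test_ari_identical_partitions():
    a = np.array([0, 0, 1, 1, 2, 2])
    assert adjusted_rand(a, a) == 1.0


def test_ari_label_swap_invariant():
    a = np.array([0, 0, 0, 1, 1, 1])
    assert adjusted_rand(a, 1 - a) == 1.0


def test_ari_worked_six_item_example():
    """Independent evaluation of the Hubert–Arabie formula:
    n11=2, n12=1, n22=3 gives (4 - 2.8) / (6.5 - 2.8) = 12/37."""
    a = np.array([1, 1, 1, 2, 2, 2])
    b = np.array([1, 1, 2, 2, 2, 2])
    assert adjusted_rand(a, b) == pytest.approx(12 / 37, abs=1e-12)
    assert adjusted_rand(a, b) == pytest.approx(0.3243243, abs=1e-6)


def test_ari_requires_two_items():
    with pytest.raises(ValueError):
        adjusted_rand(np.array([0]), np.array([0]))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    labels=st.lists(
        st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=40
    ),
    perm_seed=st.integers(0, 100),
)
def test_ari_matches_sklearn_and_is_symmetric(labels, perm_seed):
    a = np.array([x for x, _ in labels])
    b = np.array([y for _, y in labels])
    ours = adjusted_rand(a, b)
    assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)
    assert ours == pytest.approx(adjusted_rand(b, a), abs=1e-12)
    assert ours <= 1.0
    rng = np.random.default_rng(perm_seed)
    perm = rng.permutation(4)
    assert adjusted_rand(perm[a], b) == pytest.approx(ours, abs=1e-12)


# ---------------------------------------------------------------------------
# Base clusterers
# ---------------------------------------------------------------------------

def two_clouds(n=60, d=6, separation=10.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % 2).astype(int)
    X = rng.normal(0.0, 1.0, size=(n, d))
    X[labels == 1] += separation
    return X, labels


@pytest.mark.parametrize("method", BASE_METHODS)
def test_well_separated_clouds_recovered(method):
    X, truth = two_clouds()
    labels = run_base_clusterer(method, X, 2, seed=1)
    assert adjusted_rand(labels, truth) == 1.0


@pytest.mark.parametrize("method", BASE_METHODS)
def test_base_clusterer_deterministic(method):
    X, _ = two_clouds(seed=3)
    a = run_base_clusterer(method, X, 2, seed=7)
    b = run_base_clusterer(method, X, 2, seed=7)
    assert np.array_equal(a, b)


def test_k_equal_n_rejected():
    X, _ = two_clouds(n=10)
    with pytest.raises(ValueError):
        run_base_clusterer("kmeans_lloyd", X, 10, seed=0)
    with pytest.raises(ValueError):
        run_base_clusterer("kmeans_lloyd", X, 1, seed=0)


def test_unknown_method_rejected():
    X, _ = two_clouds(n=10)
    with pytest.raises(ValueError, match="unknown method"):
        run_base_clusterer("dbscan", X, 2, seed=0)


# ---------------------------------------------------------------------------
# Ensemble bookkeeping
# ---------------------------------------------------------------------------

def test_build_ensemble_bookkeeping():
    X, _ = two_clouds(n=50)
    config = EnsembleConfig(
        methods=("kmeans_lloyd", "pam"), reps_per_method=3, master_seed=5
    )
    runs = build_ensemble(X, config)
    assert len(runs) == 6
    assert all(len(r.item_indices) == 40 for r in runs)  # ceil(0.8 * 50)
    assert all(len(r.labels) == len(r.item_indices) for r in runs)


def test_build_ensemble_reproducible():
    X, _ = two_clouds(n=40)
    config = EnsembleConfig(methods=("pam",), reps_per_method=4, master_seed=11)
    a = build_ensemble(X, config)
    b = build_ensemble(X, config)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.item_indices, rb.item_indices)
        assert np.array_equal(ra.labels, rb.labels)
        assert ra.seed == rb.seed == run_seed(11, ra.method, a.index(ra) % 4)


def test_subsample_coverage_expectation():
    """Each item is sampled reps x methods x fraction times in expectation."""
    X, _ = two_clouds(n=100)
    config = EnsembleConfig(
        methods=("kmeans_lloyd", "pam"), reps_per_method=20, master_seed=3
    )
    runs = build_ensemble(X, config)
    counts = np.zeros(100)
    for r in runs:
        counts[r.item_indices] += 1
    expected = 2 * 20 * 0.8
    assert abs(counts.mean() - expected) / expected < 0.05


# ---------------------------------------------------------------------------
# mean pairwise ARI
# ---------------------------------------------------------------------------

def full_run(labels, method="kmeans_lloyd", seed=0):
    labels = np.asarray(labels)
    return ClusterRun(
        method=method,
        seed=seed,
        item_indices=np.arange(len(labels)),
        labels=labels,
    )


def test_mean_pairwise_ari_identical_runs():
    runs = [full_run([0, 0, 1, 1, 0, 1]) for _ in range(4)]
    assert mean_pairwise_ari(runs) == 1.0


def test_mean_pairwise_ari_is_mean_of_pairs():
    a, b, c = [0, 0, 1, 1], [0, 1, 0, 1], [0, 0, 0, 1]
    runs = [full_run(x) for x in (a, b, c)]
    expected = np.mean(
        [adjusted_rand(np.array(x), np.array(y))
         for x, y in itertools.combinations((a, b, c), 2)]
    )
    assert mean_pairwise_ari(runs) == pytest.approx(expected)


def test_mean_pairwise_ari_random_labels_centred_at_zero():
    rng = np.random.default_rng(0)
    runs = [full_run(rng.integers(0, 2, size=200)) for _ in range(12)]
    assert abs(mean_pairwise_ari(runs)) <= 0.05


def test_mean_pairwise_ari_needs_two_runs():
    with pytest.raises(ValueError):
        mean_pairwise_ari([full_run([0, 1])])


# ---------------------------------------------------------------------------
# Alignment and voting
# ---------------------------------------------------------------------------

def test_relabel_consistent_runs_unchanged():
    runs = [full_run([0, 0, 1, 1]) for _ in range(3)]
    aligned, ref, _ = relabel_runs(runs, 4, 2)
    for r in aligned:
        assert np.array_equal(r.labels, [0, 0, 1, 1])


def test_relabel_undoes_swap():
    base = np.array([0, 0, 1, 1, 0])
    runs = [full_run(base), full_run(base), full_run(1 - base)]
    aligned, ref, _ = relabel_runs(runs, 5, 2)
    for r in aligned:
        assert np.array_equal(r.labels, base)


def test_relabel_never_decreases_agreement():
    rng = np.random.default_rng(4)
    runs = [full_run(rng.integers(0, 2, size=30)) for _ in range(3)]

    def total_agreement(rs):
        return sum(
            (a.labels == b.labels).mean()
            for a, b in itertools.combinations(rs, 2)
        )

    aligned, _, _ = relabel_runs(runs, 30, 2)
    assert total_agreement(aligned) >= total_agreement(runs) - 1e-12


def test_majority_vote_unanimous_and_mode():
    runs = [full_run([0, 0, 1]), full_run([0, 0, 1]), full_run([0, 1, 1])]
    labels, share, votes, _ = majority_vote(runs, 3, 2)
    assert list(labels) == [0, 0, 1]
    assert share[0] == 1.0
    assert share[1] == pytest.approx(2 / 3)
    assert list(votes) == [3, 3, 3]


def test_majority_vote_matches_exhaustive_oracle():
    """For n <= 8 the consensus equals the assignment maximising total
    vote agreement over all 2^n labelings (per-item independence makes the
    optimum the per-item mode; verified by brute force)."""
    rng = np.random.default_rng(9)
    n = 7
    runs = []
    for i in range(5):
        idx = np.sort(rng.choice(n, size=6, replace=False))
        runs.append(
            ClusterRun("pam", i, idx, rng.integers(0, 2, size=6))
        )
    votes = np.zeros((n, 2))
    for r in runs:
        np.add.at(votes, (r.item_indices, r.labels), 1)
    has_tie_or_zero = ((votes[:, 0] == votes[:, 1])).any()
    best_score, best = -1, None
    for assignment in itertools.product([0, 1], repeat=n):
        score = sum(votes[i, a] for i, a in enumerate(assignment))
        if score > best_score:
            best_score, best = score, assignment
    labels, _, _, _ = majority_vote(runs, n, 2, X=rng.normal(size=(n, 3)))
    achieved = sum(votes[i, a] for i, a in enumerate(labels))
    assert achieved == best_score
    if not has_tie_or_zero:
        assert list(labels) == list(best)


def test_tied_votes_fall_back_to_centroids():
    X = np.array([[0.0], [0.0], [10.0], [10.0], [9.5]])
    runs = [
        full_run([0, 0, 1, 1, 0]),
        full_run([0, 0, 1, 1, 1]),
    ]
    labels, share, votes, n_fallback = majority_vote(runs, 5, 2, X=X)
    assert n_fallback == 1
    assert labels[4] == 1  # nearest centroid is the high cluster
    assert list(labels[:4]) == [0, 0, 1, 1]


def test_assign_unvoted_tie_takes_lower_index():
    from gpclusters.ensemble import assign_unvoted

    centroids = np.array([[0.0, 0.0], [2.0, 0.0]])
    assert assign_unvoted(np.array([1.0, 0.0]), centroids) == 0
    assert assign_unvoted(np.array([2.0, 0.0]), centroids) == 1


def test_consensus_invariant_to_run_order_and_global_flip():
    X, _ = two_clouds(n=40, separation=6.0)
    config = EnsembleConfig(
        methods=("kmeans_lloyd", "pam"), reps_per_method=5, master_seed=2
    )
    runs = build_ensemble(X, config)
    aligned, _, _ = relabel_runs(runs, 40, 2)
    labels, *_ = majority_vote(aligned, 40, 2, X=X)
    shuffled = list(reversed(runs))
    aligned2, _, _ = relabel_runs(shuffled, 40, 2)
    labels2, *_ = majority_vote(aligned2, 40, 2, X=X)
    assert adjusted_rand(labels, labels2) == 1.0
    flipped = [
        ClusterRun(r.method, r.seed, r.item_indices, 1 - r.labels) for r in runs
    ]
    aligned3, _, _ = relabel_runs(flipped, 40, 2)
    labels3, *_ = majority_vote(aligned3, 40, 2, X=X)
    assert adjusted_rand(labels, labels3) == 1.0


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

def test_model_fit_recovers_separated_clouds_and_is_deterministic():
    X, truth = two_clouds(n=60, separation=8.0, seed=5)
    model = ConsensusClustering(
        X, k=2, methods=("kmeans_lloyd", "hierarchical_ward", "pam"),
        reps_per_method=5,
    )
    result = model.fit(master_seed=3)
    assert adjusted_rand(result.labels, truth) == 1.0
    assert result.mean_pairwise_ari == pytest.approx(1.0)
    again = model.fit(master_seed=3)
    assert np.array_equal(result.labels, again.labels)
    assert np.array_equal(result.vote_share, again.vote_share)
    # a different seed still yields a valid, near-identical partition here
    other = model.fit(master_seed=4)
    assert adjusted_rand(result.labels, other.labels) == 1.0


def test_result_summary_and_predict():
    X, truth = two_clouds(n=40, separation=8.0)
    result = ConsensusClustering(
        X, k=2, methods=("kmeans_lloyd",), reps_per_method=5
    ).fit(master_seed=0)
    text = result.summary()
    assert "mean pairwise ARI" in text and "cluster 0" in text
    cents = result.centroids()
    assert list(result.predict(cents)) == [0, 1]
    frame = result.to_frame()
    assert set(frame.columns) == {"practice_id", "cluster", "vote_share", "n_votes"}
    assert (frame["vote_share"] > 0).all()


def test_config_validation():
    with pytest.raises(ValueError):
        EnsembleConfig(k=1)
    with pytest.raises(ValueError):
        EnsembleConfig(subsample_fraction=0.0)
    with pytest.raises(ValueError):
        EnsembleConfig(methods=("kmeans_lloyd", "spectral"))
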