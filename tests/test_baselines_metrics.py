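import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scvdmc import (
    ExpressionDomain,
    MultiDomainDataset,
    adjusted_rand_index,
    clustering_error,
    evaluation_report,
    pooled_kmeans,
    separated_kmeans,
    variance_feature_selection,
)


def brute_force_error(pred, truth):
    """Best one-to-one matching by enumerating all cluster permutations,
    padding the smaller side with unused labels."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    pu, tu = list(np.unique(pred)), list(np.unique(truth))
    size = max(len(pu), len(tu))
    pu = pu + [f"pad{i}" for i in range(size - len(pu))]
    tu = tu + [f"pad{i}" for i in range(size - len(tu))]
    best = 0
    for perm in itertools.permutations(range(size)):
        agree = sum(
            np.sum((pred == pu[i]) & (truth == tu[perm[i]])) for i in range(size)
        )
        best = max(best, agree)
    return 1.0 - best / pred.size


def small_dataset(rng, m=5, D=2, n=8):
    domains = [
        ExpressionDomain(f"d{d}", rng.normal(size=(m, n)), [f"d{d}c{i}" for i in range(n)])
        for d in range(D)
    ]
    return MultiDomainDataset([f"g{i}" for i in range(m)], domains)


# ---- variance-based gene selection -------------------------------------------------


def test_variance_selection_picks_largest_variance():
    X = np.array([[1.0, 1.0, 1.0], [0.0, 4.0, 2.0], [0.0, 1.0, 2.0]])
    ds = MultiDomainDataset(
        ["g0", "g1", "g2"], [ExpressionDomain("d0", X, ["a", "b", "c"])]
    )
    assert variance_feature_selection(ds, 1).tolist() == [1]
    assert variance_feature_selection(ds, 3).tolist() == [0, 1, 2]


def test_variance_selection_constant_data_ties_to_lowest_index():
    X = np.ones((4, 3))
    ds = MultiDomainDataset(
        [f"g{i}" for i in range(4)], [ExpressionDomain("d0", X, ["a", "b", "c"])]
    )
    assert variance_feature_selection(ds, 2).tolist() == [0, 1]


def test_variance_selection_bounds(rng):
    ds = small_dataset(rng)
    with pytest.raises(ValueError):
        variance_feature_selection(ds, 0)
    with pytest.raises(ValueError):
        variance_feature_selection(ds, 6)


# ---- k-means baselines -------------------------------------------------------------


def test_pooled_equals_separated_on_single_domain(rng):
    ds = small_dataset(rng, D=1, n=20)
    p = pooled_kmeans(ds, 3, seed=0)
    s = separated_kmeans(ds, 3, seed=0)
    assert np.array_equal(p[0].labels, s[0].labels)
    assert p[0].domain_id == s[0].domain_id == "d0"


def test_separated_recovers_separated_point_masses():
    X = np.repeat([[0.0, 50.0, -50.0]], 4, axis=0)[:, [0, 1, 2, 0, 1, 2]]
    ds = MultiDomainDataset(
        [f"g{i}" for i in range(4)],
        [ExpressionDomain("d0", X, [f"c{i}" for i in range(6)])],
    )
    labels = separated_kmeans(ds, 3, seed=1)[0].labels
    assert adjusted_rand_index(labels, [0, 1, 2, 0, 1, 2]) == 1.0


def test_baselines_deterministic_given_seed(rng):
    ds = small_dataset(rng, D=2, n=15)
    for f in (pooled_kmeans, separated_kmeans):
        a = f(ds, 2, seed=9)
        b = f(ds, 2, seed=9)
        for la, lb in zip(a, b):
            assert np.array_equal(la.labels, lb.labels)


def test_gene_subset_restricts_clustering():
    rng = np.random.default_rng(0)
    # only gene 0 separates; genes 1-3 are strong confounders
    sig = np.array([0.0] * 5 + [30.0] * 5)
    X = np.vstack([sig, rng.normal(scale=20.0, size=(3, 10))])
    ds = MultiDomainDataset(
        [f"g{i}" for i in range(4)],
        [ExpressionDomain("d0", X, [f"c{i}" for i in range(10)])],
    )
    labels = pooled_kmeans(ds, 2, gene_subset=[0], seed=0)[0].labels
    assert adjusted_rand_index(labels, [0] * 5 + [1] * 5) == 1.0


# ---- metrics -----------------------------------------------------------------------


def test_clustering_error_examples():
    assert clustering_error([1, 1, 2, 2], [1, 1, 2, 2]) == 0.0
    assert clustering_error([2, 2, 1, 1], [1, 1, 2, 2]) == 0.0  # relabeling
    assert clustering_error([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(0.25)


def test_clustering_error_matches_brute_force(rng):
    for _ in range(100):
        n = int(rng.integers(2, 12))
        kp, kt = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        pred = rng.integers(0, kp, size=n)
        truth = rng.integers(0, kt, size=n)
        assert clustering_error(pred, truth) == pytest.approx(
            brute_force_error(pred, truth)
        )


@settings(max_examples=40, derandomize=True)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=12),
    st.data(),
)
def test_clustering_error_symmetric_and_relabel_invariant(labels, data):
    other = data.draw(
        st.lists(st.integers(0, 3), min_size=len(labels), max_size=len(labels))
    )
    pred, truth = np.array(labels), np.array(other)
    assert clustering_error(pred, truth) == pytest.approx(clustering_error(truth, pred))
    perm = {v: 3 - v for v in range(4)}
    relabeled = np.array([perm[v] for v in pred])
    assert clustering_error(relabeled, truth) == pytest.approx(
        clustering_error(pred, truth)
    )


def test_clustering_error_length_mismatch():
    with pytest.raises(ValueError):
        clustering_error([1, 2], [1, 2, 3])


def test_ari_examples():
    assert adjusted_rand_index([1, 2, 3], [1, 2, 3]) == 1.0
    assert adjusted_rand_index([1, 1, 1, 1], [1, 2, 1, 2]) == 0.0
    assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)


def test_ari_relabel_invariant_and_identity(rng):
    for _ in range(20):
        lab = rng.integers(0, 4, size=30)
        assert adjusted_rand_index(lab, lab) == 1.0
        assert adjusted_rand_index(lab + 10, lab) == 1.0


def test_ari_validations():
    with pytest.raises(ValueError):
        adjusted_rand_index([1], [1])
    with pytest.raises(ValueError):
        adjusted_rand_index([1, 2], [1, 2, 3])


def test_evaluation_report_structure():
    preds = [np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0])]
    truths = [np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1])]
    rep = evaluation_report(preds, truths, ["a", "b"])
    assert rep["per_domain"]["a"]["error"] == 0.0
    assert rep["per_domain"]["b"]["error"] == 0.0  # relabeling within domain
    assert rep["per_domain"]["b"]["ari"] == 1.0
    assert rep["pooled"]["n_cells"] == 8
    # globally, the two domains' label spaces conflict: pooled error > 0
    assert rep["pooled"]["error"] > 0.0
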