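import numpy as np
import pytest

from scvdmc import (
    HyperParams,
    elbow_scan,
    elbow_statistic,
    fit,
    objective,
    w_upper_bound_implemented,
    w_upper_bound_printed,
)
from scvdmc.data import ExpressionDomain, FitResult, MultiDomainDataset
from scvdmc.model_selection import alpha_diagnostic, alpha_scan, center_hessian
from tests.conftest import make_dataset


@pytest.mark.parametrize(
    "k, D, alpha, c_min, expected",
    [
        (2, 2, 0.0, 1, 1.0),
        (3, 3, 0.5, 1, 1.875),  # 9/8 + 0.5*27*2/(2*9*2)
        (2, 5, 0.0, 3, 3.0),  # alpha=0: c_min scales the k^2/(4(k-1)) term
    ],
)
def test_printed_bound_closed_form(k, D, alpha, c_min, expected):
    assert w_upper_bound_printed(k, D, alpha, c_min) == pytest.approx(expected)


def test_printed_bound_independent_of_D_when_alpha_zero():
    vals = {w_upper_bound_printed(4, D, 0.0, 2) for D in (1, 2, 5, 9)}
    assert len(vals) == 1


def test_bounds_monotone_in_c_min():
    for f in (w_upper_bound_printed, w_upper_bound_implemented):
        vals = [f(3, 2, 0.7, c) for c in (1, 2, 5, 10)]
        assert vals == sorted(vals)


def test_printed_bound_carries_extra_factor_k():
    k, D, alpha = 4, 3, 2.0
    gap = w_upper_bound_printed(k, D, alpha, 1) - w_upper_bound_implemented(k, D, alpha, 1)
    expected = alpha * (k**3 - k**2) * (D - 1) / (2 * D**2 * (k - 1))
    assert gap == pytest.approx(expected)


def test_invalid_bound_arguments():
    with pytest.raises(ValueError):
        w_upper_bound_printed(1, 2, 0.0, 1)
    with pytest.raises(ValueError):
        w_upper_bound_implemented(3, 0, 0.0, 1)


def test_hessian_psd_at_implemented_bound(rng):
    """At w equal to the bound the center-subproblem Hessian stays PSD for
    any cluster-size vector respecting c_min (Gershgorin guarantee)."""
    for _ in range(50):
        k = int(rng.integers(2, 7))
        D = int(rng.integers(1, 5))
        alpha = float(rng.uniform(0, 3))
        c_min = int(rng.integers(1, 6))
        sizes = rng.integers(c_min, c_min + 20, size=k)
        w = w_upper_bound_implemented(k, D, alpha, c_min)
        H = center_hessian(sizes, D, w, alpha)
        assert np.linalg.eigvalsh(H).min() >= -1e-10


def test_hessian_psd_trivially_at_w_zero(rng):
    H = center_hessian([3, 1, 7], D=2, w=0.0, alpha=1.5)
    assert np.linalg.eigvalsh(H).min() >= 0


def _fit_result_for(ds, U, V, B):
    return FitResult(U=U, V=V, B=np.asarray(B))


def test_elbow_statistic_hand_example():
    # one selected gene, two cells at 0 and 2 sharing a center at 1
    ds = MultiDomainDataset(
        ["g0", "gpad"],
        [ExpressionDomain("d0", np.array([[0.0, 2.0], [0.0, 0.0]]), ["a", "b"])],
    )
    U = [np.array([[1.0], [0.0]])]
    V = [np.array([[1], [1]])]
    res = _fit_result_for(ds, U, V, [1, 0])
    assert elbow_statistic(ds, res) == pytest.approx(2.0)  # (0-1)^2 + (2-1)^2


def test_elbow_statistic_zero_when_cells_at_centers(rng, dataset_factory, state_factory):
    ds = dataset_factory(rng, m=4, k=2, D=2, n=6)
    U, V, B = state_factory(rng, ds, k=2)
    exact_domains = [
        ExpressionDomain(d.domain_id, Ud @ Vd.T, list(d.cell_ids))
        for d, Ud, Vd in zip(ds.domains, U, V)
    ]
    exact = MultiDomainDataset(list(ds.gene_ids), exact_domains)
    assert elbow_statistic(exact, _fit_result_for(exact, U, V, B)) == pytest.approx(0.0)


def test_elbow_statistic_is_twice_reconstruction_term(rng, dataset_factory, state_factory):
    ds = dataset_factory(rng, m=6, k=3, D=2, n=10)
    U, V, B = state_factory(rng, ds, k=3)
    res = _fit_result_for(ds, U, V, B)
    terms = objective(ds, U, V, B, w=0.0, alpha=0.0)
    assert elbow_statistic(ds, res) == pytest.approx(2.0 * terms.reconstruction)


def test_elbow_scan_single_k_equals_statistic(rng):
    ds = make_dataset(rng, m=8, k=3, D=2, n=16)
    params = HyperParams(k=3, lam=4, w=0.2, alpha=0.2, seed=1)
    points = elbow_scan(ds, [3], params, repeats=1)
    assert len(points) == 1
    res = fit(ds, params)
    assert points[0].Ts == pytest.approx(elbow_statistic(ds, res))


def test_elbow_scan_rejects_k_out_of_range(rng):
    ds = make_dataset(rng, m=8, k=3, D=2, n=10)
    with pytest.raises(ValueError):
        elbow_scan(ds, [1], HyperParams(k=2, lam=4, seed=0), repeats=1)


def test_alpha_diagnostic_identical_centers_is_zero():
    U = [np.arange(6.0).reshape(3, 2)] * 3
    res = FitResult(U=U, V=[np.ones((2, 2))] * 3, B=np.array([1, 1, 0]))
    assert alpha_diagnostic(res) == 0.0


def test_alpha_diagnostic_euclidean_example():
    # two domains, one cluster, centers differing by (3, 4) on selected genes
    U0 = np.array([[0.0], [0.0], [9.0]])
    U1 = np.array([[3.0], [4.0], [-2.0]])
    res = FitResult(U=[U0, U1], V=[np.ones((1, 1))] * 2, B=np.array([1, 1, 0]))
    assert alpha_diagnostic(res) == pytest.approx(5.0)


def test_alpha_diagnostic_invariant_to_common_shift(rng):
    U = [rng.normal(size=(4, 3)) for _ in range(3)]
    B = np.array([1, 0, 1, 1])
    res = FitResult(U=U, V=[np.ones((2, 3))] * 3, B=B)
    shifted = FitResult(U=[u + 7.5 for u in U], V=res.V, B=B)
    assert alpha_diagnostic(res) == pytest.approx(alpha_diagnostic(shifted))


def test_alpha_diagnostic_needs_two_domains():
    res = FitResult(U=[np.ones((2, 2))], V=[np.ones((2, 2))], B=np.array([1, 1]))
    with pytest.raises(ValueError):
        alpha_diagnostic(res)


def test_alpha_scan_returns_curve_and_plateau_choice(rng):
    ds = make_dataset(rng, m=8, k=2, D=2, n=14)
    params = HyperParams(k=2, lam=4, w=0.2, alpha=0.0, seed=2)
    curve, chosen = alpha_scan(ds, params, alphas=(0.0, 1.0, 5.0), repeats=1)
    assert [a for a, _ in curve] == [0.0, 1.0, 5.0]
    assert chosen in (0.0, 1.0, 5.0)
    assert all(v >= 0 for _, v in curve)
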