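"""Hyperparameter utilities: the PSD bound on w, the elbow statistic for k,
and the cross-domain center-agreement diagnostic for alpha.

The center subproblem is convex exactly when its ``k x k`` Hessian

    H = V^T V - (2w/k) Psi + (2 alpha / D) Phi_dd I_k

is positive semidefinite. Requiring diagonal dominance (Gershgorin circle
theorem) gives a sufficient upper bound on ``w`` in terms of the smallest
cluster size ``c_min``; the "loose" form sets ``c_min = 1`` since no cluster
is ever left empty.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .data import FitResult, HyperParams, MultiDomainDataset
from .solver import fit, objective

__all__ = [
    "ElbowPoint",
    "BoundReport",
    "w_upper_bound_printed",
    "w_upper_bound_implemented",
    "bound_report",
    "center_hessian",
    "elbow_statistic",
    "elbow_scan",
    "alpha_diagnostic",
    "alpha_scan",
]


@dataclass(frozen=True)
class ElbowPoint:
    """Mean within-clusters sum of squares on selected genes at one k."""

    k: int
    Ts: float


@dataclass(frozen=True)
class BoundReport:
    printed_bound: float
    implemented_bound: float
    c_min: int


def _check_bound_args(k: int, D: int, alpha: float, c_min: int) -> None:
    if k < 2:
        raise ValueError("k must be >= 2 (the bound divides by k - 1)")
    if D < 1:
        raise ValueError("D must be >= 1")
    if c_min < 1:
        raise ValueError("c_min must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")


def w_upper_bound_printed(k: int, D: int, alpha: float, c_min: int = 1) -> float:
    """Published closed-form bound: k^2 c_min / (4(k-1)) + alpha k^3 (D-1) / (2 D^2 (k-1)).

    This form carries an extra factor of ``k`` on the alpha term relative to
    the bound of the Hessian actually assembled by the default center update;
    it is kept for comparison with the original derivation.
    """
    _check_bound_args(k, D, alpha, c_min)
    return k**2 * c_min / (4.0 * (k - 1)) + alpha * k**3 * (D - 1) / (2.0 * D**2 * (k - 1))


def w_upper_bound_implemented(k: int, D: int, alpha: float, c_min: int = 1) -> float:
    """Largest w keeping the implemented center-update Hessian diagonally
    dominant (hence PSD) for every cluster-size vector with min size >= c_min.

    Diagonal dominance of ``H`` requires
    ``c_i + 2 alpha (D-1)/D^2 - 2w(k-1)/k^2 >= 2w(k-1)/k^2``, i.e.
    ``w <= k^2 c_min / (4(k-1)) + alpha k^2 (D-1) / (2 D^2 (k-1))``.
    """
    _check_bound_args(k, D, alpha, c_min)
    return k**2 * c_min / (4.0 * (k - 1)) + alpha * k**2 * (D - 1) / (2.0 * D**2 * (k - 1))


def bound_report(k: int, D: int, alpha: float, c_min: int = 1) -> BoundReport:
    return BoundReport(
        printed_bound=w_upper_bound_printed(k, D, alpha, c_min),
        implemented_bound=w_upper_bound_implemented(k, D, alpha, c_min),
        c_min=c_min,
    )


def center_hessian(
    cluster_sizes: Sequence[int], D: int, w: float, alpha: float, scaling: str = "derived"
) -> np.ndarray:
    """Assemble the k x k Hessian of the center subproblem for given cluster
    sizes; used for eigenvalue checks of the bound."""
    c = np.asarray(cluster_sizes, dtype=float)
    k = c.size
    afac = alpha * (k if scaling == "printed" else 1.0)
    Psi = np.eye(k) - np.full((k, k), 1.0 / k)
    return np.diag(c) - (2.0 * w / k) * Psi + (2.0 * afac / D) * ((D - 1) / D) * np.eye(k)


def elbow_statistic(dataset: MultiDomainDataset, result: FitResult) -> float:
    """Within-clusters sum of squares on the selected genes,
    ``sum_d ||D_B (X^(d) - U^(d) V^(d)^T)||_F^2`` (twice the reconstruction
    term of the objective)."""
    terms = objective(dataset, result.U, result.V, result.B, w=0.0, alpha=0.0)
    return 2.0 * terms.reconstruction


def elbow_scan(
    dataset: MultiDomainDataset,
    k_values: Sequence[int],
    params: HyperParams,
    repeats: int = 10,
) -> list[ElbowPoint]:
    """Mean elbow statistic per candidate k, averaged over ``repeats``
    re-seeded fits. Scanning k and reading off the curve's elbow is the
    standard way to choose the number of cell types."""
    n_min = min(dataset.n_cells)
    points = []
    for k in k_values:
        if not 2 <= k <= n_min:
            raise ValueError(f"k={k} outside [2, {n_min}] for this dataset")
        ts = []
        for r in range(repeats):
            p = replace(params, k=k, seed=params.seed + r)
            res = fit(dataset, p)
            ts.append(elbow_statistic(dataset, res))
        points.append(ElbowPoint(k=k, Ts=float(np.mean(ts))))
    return points


def alpha_diagnostic(result: FitResult) -> float:
    """Total cross-domain disagreement of matched cluster centers.

    Sum over cluster indices j and unordered domain pairs (d, l) of the
    Euclidean distance between the j-th center of domain d and of domain l,
    restricted to the selected genes. Clusters are matched by column index,
    which the agreement term and the common initialization align. Increasing
    alpha drives this quantity down; the smallest alpha at which it plateaus
    is a good operating point.
    """
    D = len(result.U)
    if D < 2:
        raise ValueError("the diagnostic needs at least two domains")
    sel = np.asarray(result.B).astype(bool)
    total = 0.0
    for d in range(D):
        Ud = result.U[d][sel]
        for l in range(d + 1, D):
            diff = Ud - result.U[l][sel]
            total += float(np.sum(np.sqrt(np.sum(diff * diff, axis=0))))
    return total


DEFAULT_ALPHA_GRID = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


def alpha_scan(
    dataset: MultiDomainDataset,
    params: HyperParams,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    repeats: int = 1,
    plateau_rtol: float = 0.10,
) -> tuple[list[tuple[float, float]], float]:
    """Scan alpha and return (alpha, mean diagnostic) pairs plus the selected
    alpha: the smallest one whose diagnostic is within ``plateau_rtol`` of
    the plateau (the value at the largest alpha scanned)."""
    if dataset.n_domains < 2:
        raise ValueError("alpha tuning needs at least two domains")
    curve = []
    for a in alphas:
        vals = []
        for r in range(repeats):
            p = replace(params, alpha=float(a), seed=params.seed + r)
            vals.append(alpha_diagnostic(fit(dataset, p)))
        curve.append((float(a), float(np.mean(vals))))
    plateau = curve[-1][1]
    chosen = curve[-1][0]
    for a, v in curve:
        if abs(v - plateau) <= plateau_rtol * max(plateau, 1e-12):
            chosen = a
            break
    return curve, chosen
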