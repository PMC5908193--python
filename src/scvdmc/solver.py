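"""Alternating-minimization solver for variance-driven multitask clustering.

The model clusters ``D`` single-cell populations (domains) jointly. Each
domain ``d`` with expression matrix ``X^(d)`` (``m x n^(d)``) gets its own
cluster centers ``U^(d)`` (``m x k``) and one-hot assignments ``V^(d)``
(``n^(d) x k``); a single binary vector ``B`` with ``sum(B) = lam`` selects
the marker genes shared by all domains. The objective is

    J = 1/2 sum_d ||D_B (X^(d) - U^(d) V^(d)^T)||_F^2
        - w   sum_d sum_i B_i Var(U^(d)_{i,:})
        + a   sum_{i,j} B_i Var([U^(1)_{i,j}, ..., U^(D)_{i,j}])

with population variances (1/k and 1/D normalization). The first term is the
k-means reconstruction error on the selected genes, the second rewards
spread-out centers within a domain (marker genes separate cell types), the
third penalizes disagreement of matched centers across domains.

Minimization alternates exactly three closed-form block updates: marker
selection (sort m linear coefficients), assignments (nearest selected-gene
center), and centers (one k x k linear solve shared by all selected genes).
Each block update cannot increase the objective as long as ``w`` stays below
the Gershgorin bound that keeps the center-subproblem Hessian positive
semidefinite.

The center stationarity system implemented here is derived directly from the
objective above: ``H = V^T V - (2w/k) Psi + (2a/D) Phi_dd I`` with centering
matrices ``Psi = I_k - 1/k`` and ``Phi = I_D - 1/D``. A published variant of
the same update carries an extra factor ``k`` on the alpha terms; it is
available via ``scaling="printed"`` for comparison but is not the default
because it is not the gradient of the objective actually minimized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.cluster import KMeans

from .data import ExpressionDomain, FitResult, HyperParams, MultiDomainDataset

__all__ = [
    "row_variance",
    "cross_domain_variance",
    "ObjectiveTerms",
    "objective",
    "update_assignments",
    "update_centers",
    "selection_coefficients",
    "select_features",
    "repair_empty_clusters",
    "fit",
]

ArrayLike = Union[np.ndarray, Sequence[float]]


def _values(X: Union[np.ndarray, ExpressionDomain]) -> np.ndarray:
    if isinstance(X, ExpressionDomain):
        return X.values
    return np.asarray(X, dtype=float)


def row_variance(u: ArrayLike) -> float:
    """Population variance of a length-k vector: (1/k) * u Psi u^T with the
    centering matrix Psi = I_k - (1/k) 11^T."""
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("cannot take the variance of an empty vector")
    return float(np.var(u))


def cross_domain_variance(y: ArrayLike) -> float:
    """Population variance of one center entry stacked across the D domains.

    Zero when D = 1 (a single domain imposes no agreement constraint).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot take the variance of an empty vector")
    return float(np.var(y))


@dataclass(frozen=True)
class ObjectiveTerms:
    """Objective value and its three components (unweighted terms).

    ``total = reconstruction - w * center_separation + alpha * cross_domain``.
    """

    total: float
    reconstruction: float
    center_separation: float
    cross_domain: float


def _check_shapes(dataset: MultiDomainDataset, U, V, B) -> None:
    m, D = dataset.n_genes, dataset.n_domains
    if len(U) != D or len(V) != D:
        raise ValueError(f"expected {D} center/assignment matrices, got {len(U)}/{len(V)}")
    B = np.asarray(B)
    if B.shape != (m,):
        raise ValueError(f"B has shape {B.shape}, expected ({m},)")
    for dom, Ud, Vd in zip(dataset.domains, U, V):
        if Ud.shape[0] != m or Vd.shape[0] != dom.n_cells or Ud.shape[1] != Vd.shape[1]:
            raise ValueError(
                f"shape mismatch in domain {dom.domain_id!r}: X {dom.values.shape}, "
                f"U {Ud.shape}, V {Vd.shape}"
            )


def objective(
    dataset: MultiDomainDataset,
    U: Sequence[np.ndarray],
    V: Sequence[np.ndarray],
    B: np.ndarray,
    w: float,
    alpha: float,
) -> ObjectiveTerms:
    """Evaluate the multitask clustering objective and its components."""
    _check_shapes(dataset, U, V, B)
    sel = np.asarray(B).astype(bool)
    recon = 0.0
    sep = 0.0
    for dom, Ud, Vd in zip(dataset.domains, U, V):
        R = dom.values[sel] - Ud[sel] @ Vd.T
        recon += 0.5 * float(np.sum(R * R))
        if sel.any():
            sep += float(np.sum(np.var(Ud[sel], axis=1)))
    if dataset.n_domains > 1 and sel.any():
        stacked = np.stack([Ud[sel] for Ud in U])  # (D, lam, k)
        cross = float(np.sum(np.var(stacked, axis=0)))
    else:
        cross = 0.0
    total = recon - w * sep + alpha * cross
    return ObjectiveTerms(total, recon, sep, cross)


def update_assignments(
    X: Union[np.ndarray, ExpressionDomain],
    U: np.ndarray,
    B: np.ndarray,
) -> np.ndarray:
    """Assign every cell one-hot to the nearest center in selected-gene space.

    Distances are squared Euclidean over genes with ``B_i = 1`` only; ties go
    to the lowest cluster index.
    """
    Xv = _values(X)
    sel = np.asarray(B).astype(bool)
    if not sel.any():
        raise ValueError("B selects no genes; at least one marker is required")
    Xs = Xv[sel]  # (lam, n)
    Us = U[sel]  # (lam, k)
    # d2[c, j] = ||Xs[:, c] - Us[:, j]||^2, expanded to avoid the lam x n x k cube
    d2 = (
        np.sum(Xs * Xs, axis=0)[:, None]
        - 2.0 * (Xs.T @ Us)
        + np.sum(Us * Us, axis=0)[None, :]
    )
    assign = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    V = np.zeros((Xv.shape[1], U.shape[1]), dtype=int)
    V[np.arange(Xv.shape[1]), assign] = 1
    return V


def update_centers(
    d: int,
    dataset: MultiDomainDataset,
    V: Sequence[np.ndarray],
    U_all: Sequence[np.ndarray],
    B: np.ndarray,
    w: float,
    alpha: float,
    scaling: str = "derived",
) -> np.ndarray:
    """Solve the center subproblem for domain ``d`` with everything else fixed.

    For selected genes the unique stationary point of the (convex, for ``w``
    below the bound) row subproblem is found by one shared ``k x k``
    factorization; non-selected genes do not enter the objective and their
    rows are maintained as ordinary per-cluster means so that they carry
    up-to-date selection coefficients into the next iteration.
    """
    if scaling not in ("derived", "printed"):
        raise ValueError("scaling must be 'derived' or 'printed'")
    X = dataset.domains[d].values
    Vd = np.asarray(V[d], dtype=float)
    k = Vd.shape[1]
    D = dataset.n_domains
    counts = Vd.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError(f"domain {dataset.domains[d].domain_id!r} has an empty cluster")
    sel = np.asarray(B).astype(bool)

    afac = alpha * (k if scaling == "printed" else 1.0)
    Psi = np.eye(k) - np.full((k, k), 1.0 / k)
    phi_dd = (D - 1) / D
    H = np.diag(counts) - (2.0 * w / k) * Psi + (2.0 * afac / D) * phi_dd * np.eye(k)

    U_new = np.empty_like(U_all[d])
    # non-selected rows: plain per-cluster means (well-defined since no empty cluster)
    if (~sel).any():
        U_new[~sel] = (X[~sel] @ Vd) / counts

    if sel.any():
        rhs = Vd.T @ X[sel].T  # (k, lam)
        if D > 1 and afac > 0:
            others = sum(U_all[l][sel] for l in range(D) if l != d)  # (lam, k)
            # Phi_dl = -1/D for l != d, moved to the right-hand side
            rhs = rhs + (2.0 * afac / (D * D)) * others.T
        eigs = np.linalg.eigvalsh((H + H.T) / 2.0)
        if eigs.min() <= 1e-10 * max(1.0, float(np.abs(eigs).max())):
            raise ValueError(
                "center-update system is singular or indefinite: w is too large "
                "for the current cluster sizes; lower w below the PSD bound "
                "(see model_selection.w_upper_bound_implemented)"
            )
        sol = np.linalg.solve(H, rhs)  # (k, lam)
        U_new[sel] = sol.T
    return U_new


def selection_coefficients(
    dataset: MultiDomainDataset,
    U: Sequence[np.ndarray],
    V: Sequence[np.ndarray],
    w: float,
    alpha: float,
) -> np.ndarray:
    """Per-gene linear coefficients of the marker-selection subproblem.

    c_i = 1/2 sum_d ||X^(d)_{i,:} - U^(d)_{i,:} V^(d)^T||^2
          - w sum_d Var(U^(d)_{i,:}) + alpha sum_j Var over domains of U_{i,j}.

    Genes with small (possibly negative) coefficients are good markers:
    low reconstruction error, well-separated centers within each domain,
    and centers that agree across domains.
    """
    m = dataset.n_genes
    recon = np.zeros(m)
    sep = np.zeros(m)
    for dom, Ud, Vd in zip(dataset.domains, U, V):
        R = dom.values - Ud @ Vd.T
        recon += 0.5 * np.sum(R * R, axis=1)
        sep += np.var(Ud, axis=1)
    if dataset.n_domains > 1:
        cross = np.sum(np.var(np.stack(list(U)), axis=0), axis=1)
    else:
        cross = np.zeros(m)
    return recon - w * sep + alpha * cross


def select_features(
    dataset: MultiDomainDataset,
    U: Sequence[np.ndarray],
    V: Sequence[np.ndarray],
    w: float,
    alpha: float,
    lam: int,
) -> np.ndarray:
    """Exact solution of the cardinality-constrained binary selection step.

    With the objective linear in B, the optimum puts 1s on the ``lam`` genes
    with the smallest coefficients; ties break to the lowest gene index.
    """
    m = dataset.n_genes
    if not 1 <= lam <= m:
        raise ValueError(f"lam must be in [1, {m}], got {lam}")
    coeff = selection_coefficients(dataset, U, V, w, alpha)
    order = np.argsort(coeff, kind="stable")
    B = np.zeros(m, dtype=int)
    B[order[:lam]] = 1
    return B


def repair_empty_clusters(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Re-populate empty clusters by randomly bisecting the largest cluster.

    While any column of ``V`` is all-zero, half the members of the largest
    cluster (chosen uniformly at random, remainder staying put) move to the
    lowest-indexed empty cluster. Returns a copy; no-op when no column is
    empty.
    """
    V = np.asarray(V)
    n, k = V.shape
    if not np.all(V.sum(axis=1) == 1):
        raise ValueError("V must be one-hot per row")
    if n < k:
        raise ValueError(f"cannot populate {k} clusters with {n} cells")
    V = V.copy()
    while True:
        sizes = V.sum(axis=0)
        empty = np.flatnonzero(sizes == 0)
        if empty.size == 0:
            return V
        largest = int(np.argmax(sizes))
        members = np.flatnonzero(V[:, largest] == 1)
        movers = rng.choice(members, size=members.size // 2, replace=False)
        V[movers, largest] = 0
        V[movers, empty[0]] = 1


def _onehot(labels: np.ndarray, k: int) -> np.ndarray:
    V = np.zeros((labels.size, k), dtype=int)
    V[np.arange(labels.size), labels] = 1
    return V


def _cluster_means(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    counts = V.sum(axis=0)
    return (X @ V) / counts


def _pooled_kmeans_init(
    dataset: MultiDomainDataset, k: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    pooled = dataset.pooled_values()
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        random_state=int(rng.integers(2**31)),
    ).fit(pooled.T)
    labels = km.labels_
    U, V = [], []
    start = 0
    for dom in dataset.domains:
        Vd = _onehot(labels[start : start + dom.n_cells], k)
        start += dom.n_cells
        Vd = repair_empty_clusters(Vd, rng)
        U.append(_cluster_means(dom.values, Vd))
        V.append(Vd)
    return U, V


def fit(
    dataset: MultiDomainDataset,
    params: HyperParams,
    init: Optional[FitResult] = None,
    scaling: str = "derived",
) -> FitResult:
    """Run the alternating-minimization algorithm to convergence.

    Initialization is pooled k-means over all domains (k-means++ seeding,
    best of 10 restarts) unless an explicit ``init`` provides U and V; the
    marker vector B is computed first in every iteration, from the current
    centers and assignments. The run stops when B is unchanged and the
    relative objective change falls below ``params.tol``, or at
    ``params.max_iter``. Fully deterministic given ``params.seed``.
    """
    from .model_selection import w_upper_bound_implemented  # local: avoid cycle

    k, lam = params.k, params.lam
    for dom in dataset.domains:
        if dom.n_cells < k:
            raise ValueError(
                f"domain {dom.domain_id!r} has {dom.n_cells} cells, fewer than k={k}"
            )
    if lam > dataset.n_genes:
        raise ValueError(f"lam={lam} exceeds the {dataset.n_genes}-gene index")

    rng = np.random.default_rng(params.seed)
    if init is not None:
        U = [u.copy() for u in init.U]
        V = [np.asarray(v).copy() for v in init.V]
    else:
        U, V = _pooled_kmeans_init(dataset, k, rng)

    c_min = int(min(v.sum(axis=0).min() for v in V))
    bound = w_upper_bound_implemented(k, dataset.n_domains, params.alpha, c_min)
    if params.w > bound:
        warnings.warn(
            f"w={params.w} exceeds the PSD bound {bound:.4g} for the smallest "
            f"initial cluster size {c_min}; the center update may not be a "
            "minimization",
            stacklevel=2,
        )

    B = np.zeros(dataset.n_genes, dtype=int)
    prev_B: Optional[np.ndarray] = None
    prev_obj: Optional[float] = None
    trace: list[float] = []
    converged = False
    for it in range(params.max_iter):
        B = select_features(dataset, U, V, params.w, params.alpha, lam)
        for d, dom in enumerate(dataset.domains):
            Vd = update_assignments(dom.values, U[d], B)
            V[d] = repair_empty_clusters(Vd, rng)
            U[d] = update_centers(
                d, dataset, V, U, B, params.w, params.alpha, scaling=scaling
            )
        obj = objective(dataset, U, V, B, params.w, params.alpha).total
        if not np.isfinite(obj):
            raise RuntimeError(f"objective became non-finite at iteration {it}")
        trace.append(obj)
        if (
            prev_B is not None
            and np.array_equal(B, prev_B)
            and abs(prev_obj - obj) < params.tol * max(1.0, abs(prev_obj))
        ):
            converged = True
            break
        prev_B, prev_obj = B, obj

    return FitResult(
        U=U,
        V=[np.asarray(v, dtype=int) for v in V],
        B=B,
        objective_trace=trace,
        n_iter=len(trace),
        converged=converged,
        seed=params.seed,
    )
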