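"""Core data containers for multi-population expression matrices.

A *domain* is one single-cell population (one biological replicate, donor or
patient sample). All domains share a single ordered gene index of ``m`` genes;
each domain has its own cells. Matrices are oriented genes x cells throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ExpressionDomain",
    "MultiDomainDataset",
    "HyperParams",
    "FitResult",
]


@dataclass
class ExpressionDomain:
    """Expression matrix of one cell population.

    Parameters
    ----------
    domain_id
        Human-readable identifier of the population.
    values
        ``m x n`` array of finite, typically log-scale, expression values
        (genes as rows, cells as columns).
    cell_ids
        ``n`` unique cell identifiers.
    gene_ids
        Optional per-domain gene identifiers, used only before gene-index
        alignment; once domains live inside a :class:`MultiDomainDataset`
        the canonical gene index is held by the dataset.
    """

    domain_id: str
    values: np.ndarray
    cell_ids: list[str]
    gene_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"domain {self.domain_id!r}: values must be 2-D (genes x cells)")
        if self.values.shape[1] < 1:
            raise ValueError(f"domain {self.domain_id!r}: needs at least one cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"domain {self.domain_id!r}: non-finite expression values")
        self.cell_ids = list(self.cell_ids)
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError(
                f"domain {self.domain_id!r}: {len(self.cell_ids)} cell ids for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError(f"domain {self.domain_id!r}: duplicate cell ids")
        if self.gene_ids is not None:
            self.gene_ids = list(self.gene_ids)
            if len(self.gene_ids) != self.values.shape[0]:
                raise ValueError(f"domain {self.domain_id!r}: gene id / row count mismatch")
            if len(set(self.gene_ids)) != len(self.gene_ids):
                raise ValueError(f"domain {self.domain_id!r}: duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class MultiDomainDataset:
    """``D`` expression domains over one shared, ordered gene index."""

    gene_ids: list[str]
    domains: list[ExpressionDomain]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) < 2:
            raise ValueError("need at least two genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in shared index")
        if len(self.domains) < 1:
            raise ValueError("need at least one domain")
        m = len(self.gene_ids)
        for dom in self.domains:
            if dom.n_genes != m:
                raise ValueError(
                    f"domain {dom.domain_id!r} has {dom.n_genes} genes, expected {m}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_cells(self) -> list[int]:
        return [d.n_cells for d in self.domains]

    def pooled_values(self) -> np.ndarray:
        """All cells concatenated column-wise, ``m x sum(n^(d))``."""
        return np.hstack([d.values for d in self.domains])

    def subset_genes(self, keep: np.ndarray) -> "MultiDomainDataset":
        """New dataset restricted to ``keep`` (boolean mask or index array),
        preserving gene order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        gene_ids = [self.gene_ids[i] for i in idx]
        domains = [
            ExpressionDomain(d.domain_id, d.values[idx, :], list(d.cell_ids))
            for d in self.domains
        ]
        return MultiDomainDataset(gene_ids, domains)

    def subset_cells(self, keep_per_domain: Sequence[np.ndarray]) -> "MultiDomainDataset":
        """New dataset with per-domain cell subsets (boolean masks or indices)."""
        if len(keep_per_domain) != self.n_domains:
            raise ValueError("one cell mask per domain required")
        domains = []
        for dom, keep in zip(self.domains, keep_per_domain):
            keep = np.asarray(keep)
            if keep.dtype == bool:
                idx = np.flatnonzero(keep)
            else:
                idx = keep
            domains.append(
                ExpressionDomain(
                    dom.domain_id,
                    dom.values[:, idx],
                    [dom.cell_ids[i] for i in idx],
                )
            )
        return MultiDomainDataset(list(self.gene_ids), domains)


@dataclass
class HyperParams:
    """Hyperparameters of the multitask clustering model.

    k
        Number of clusters (shared across domains).
    lam
        Number of marker genes to select (the cardinality of B).
    w
        Weight of the within-domain center-separation reward. Must stay
        below the positive-semidefiniteness bound (see
        :func:`scvdmc.model_selection.w_upper_bound_implemented`) for the
        center update to be a minimization.
    alpha
        Weight of the cross-domain center-agreement penalty.
    """

    k: int
    lam: int
    w: float = 0.0
    alpha: float = 0.0
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")

    def replace(self, **kwargs) -> "HyperParams":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    """Solution of one alternating-minimization run.

    U : list of ``m x k`` center matrices, one per domain.
    V : list of ``n^(d) x k`` one-hot assignment matrices.
    B : length-``m`` binary marker-selection vector, ``sum(B) == lam``.
    objective_trace : objective value after each completed iteration.
    """

    U: list[np.ndarray]
    V: list[np.ndarray]
    B: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: Optional[int] = None

    @property
    def labels(self) -> list[np.ndarray]:
        """Per-domain integer cluster labels (argmax of each one-hot row)."""
        return [np.argmax(v, axis=1) for v in self.V]
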