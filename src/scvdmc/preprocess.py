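"""Data-cleaning filters applied to a multi-domain dataset before clustering.

All boundary comparisons are strict, matching the conventions the filters
were defined with (a gene at exactly the mean-expression threshold is kept;
a cell expressing exactly ``min_genes`` genes is kept). "Expressed" means a
strictly positive value. Every filter returns a new dataset plus a
:class:`FilterLog` naming exactly what was removed, and is idempotent.

Read-count based cell exclusion and sub-sampling of population controls are
alignment-level steps handled upstream of this package; they can be recorded
as externally applied steps in a FilterLog for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data import FitResult, HyperParams, MultiDomainDataset
from .solver import fit as _fit
from .solver import selection_coefficients

__all__ = [
    "FilterLog",
    "log_transform",
    "filter_low_expression_genes",
    "filter_cells_min_genes",
    "filter_uniform_genes",
    "filter_genes_min_cells",
    "ExclusionLoopResult",
    "exclude_genes_iterative",
]


@dataclass
class FilterLog:
    """Record of one filtering step: what ran, what was removed."""

    step: str
    removed: list[str] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0

    def __post_init__(self) -> None:
        if self.n_before - self.n_after != len(self.removed):
            raise ValueError("FilterLog counts inconsistent with removal list")


def log_transform(
    dataset: MultiDomainDataset, pseudocount: float = 1.0, base: float = 2.0
) -> MultiDomainDataset:
    """Elementwise x -> log_base(x + pseudocount); rejects negative input."""
    domains = []
    for dom in dataset.domains:
        if np.any(dom.values < 0):
            raise ValueError(f"domain {dom.domain_id!r} has negative values")
        vals = np.log(dom.values + pseudocount) / np.log(base)
        domains.append(type(dom)(dom.domain_id, vals, list(dom.cell_ids)))
    return MultiDomainDataset(list(dataset.gene_ids), domains)


def filter_low_expression_genes(
    dataset: MultiDomainDataset, threshold: float = 1.5
) -> tuple[MultiDomainDataset, FilterLog]:
    """Drop genes whose mean over all cells pooled across domains is
    strictly below ``threshold`` (applied to already log-scale data)."""
    means = dataset.pooled_values().mean(axis=1)
    keep = means >= threshold
    removed = [g for g, k in zip(dataset.gene_ids, keep) if not k]
    return dataset.subset_genes(keep), FilterLog(
        "filter_low_expression_genes", removed, dataset.n_genes, int(keep.sum())
    )


def filter_cells_min_genes(
    dataset: MultiDomainDataset, min_genes: int = 2000
) -> tuple[MultiDomainDataset, FilterLog]:
    """Drop cells expressing (value > 0) fewer than ``min_genes`` genes."""
    masks, removed = [], []
    n_before = sum(dataset.n_cells)
    for dom in dataset.domains:
        expressed = (dom.values > 0).sum(axis=0)
        keep = expressed >= min_genes
        masks.append(keep)
        removed.extend(cid for cid, k in zip(dom.cell_ids, keep) if not k)
    out = dataset.subset_cells(masks)
    return out, FilterLog(
        "filter_cells_min_genes", removed, n_before, sum(out.n_cells)
    )


def filter_uniform_genes(
    dataset: MultiDomainDataset,
) -> tuple[MultiDomainDataset, FilterLog]:
    """Drop genes expressed uniformly (zero variance) within ANY single domain."""
    keep = np.ones(dataset.n_genes, dtype=bool)
    for dom in dataset.domains:
        keep &= np.var(dom.values, axis=1) > 0
    removed = [g for g, k in zip(dataset.gene_ids, keep) if not k]
    return dataset.subset_genes(keep), FilterLog(
        "filter_uniform_genes", removed, dataset.n_genes, int(keep.sum())
    )


def filter_genes_min_cells(
    dataset: MultiDomainDataset, min_cells: int = 3
) -> tuple[MultiDomainDataset, FilterLog]:
    """Drop genes expressed (value > 0) in fewer than ``min_cells`` cells
    pooled across all domains."""
    n_expressing = (dataset.pooled_values() > 0).sum(axis=1)
    keep = n_expressing >= min_cells
    removed = [g for g, k in zip(dataset.gene_ids, keep) if not k]
    return dataset.subset_genes(keep), FilterLog(
        "filter_genes_min_cells", removed, dataset.n_genes, int(keep.sum())
    )


@dataclass
class ExclusionLoopResult:
    """Outcome of the iterative confounder-gene exclusion loop."""

    result: FitResult
    dataset: MultiDomainDataset
    removed_per_round: list[list[str]]
    n_rounds: int
    converged: bool


def exclude_genes_iterative(
    dataset: MultiDomainDataset,
    params: HyperParams,
    exclusion_list: Iterable[str],
    top_n: int = 100,
    max_rounds: int = 10,
) -> ExclusionLoopResult:
    """Refit while confounding genes (e.g. cell-cycle genes) keep appearing
    among the top-ranked selected markers.

    After each fit, selected markers are ranked by ascending selection
    coefficient; any of the first ``top_n`` that are on the exclusion list
    are removed from the dataset and the model is refit, until the top
    markers are clean or ``max_rounds`` is hit.
    """
    excluded = set(exclusion_list)
    removed_history: list[list[str]] = []
    for _ in range(max_rounds):
        result = _fit(dataset, params)
        coeff = selection_coefficients(dataset, result.U, result.V, params.w, params.alpha)
        sel_idx = np.flatnonzero(result.B)
        ranked = sel_idx[np.argsort(coeff[sel_idx], kind="stable")][:top_n]
        bad = [dataset.gene_ids[i] for i in ranked if dataset.gene_ids[i] in excluded]
        if not bad:
            return ExclusionLoopResult(
                result, dataset, removed_history, len(removed_history) + 1, True
            )
        removed_history.append(bad)
        keep = np.array([g not in set(bad) for g in dataset.gene_ids])
        dataset = dataset.subset_genes(keep)
        if params.lam > dataset.n_genes:
            raise ValueError("exclusion removed too many genes for the requested lam")
    result = _fit(dataset, params)
    return ExclusionLoopResult(result, dataset, removed_history, max_rounds + 1, False)
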