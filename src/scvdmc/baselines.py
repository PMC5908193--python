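"""Single-task k-means baselines with optional variance-based gene selection.

These are the two reference strategies the multitask model is compared
against: k-means on the pooled cells of all populations, and k-means on each
population separately, optionally restricted to the genes of largest pooled
variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .data import MultiDomainDataset

__all__ = [
    "LabelVector",
    "variance_feature_selection",
    "pooled_kmeans",
    "separated_kmeans",
]

N_RESTARTS = 10  # k-means++ restarts; best inertia wins


@dataclass
class LabelVector:
    labels: np.ndarray
    domain_id: str

    def __len__(self) -> int:
        return self.labels.size


def variance_feature_selection(dataset: MultiDomainDataset, lam: int) -> np.ndarray:
    """Indices of the ``lam`` genes with largest variance over all pooled
    cells (ties to the lowest gene index), in ascending index order."""
    m = dataset.n_genes
    if not 1 <= lam <= m:
        raise ValueError(f"lam must be in [1, {m}], got {lam}")
    var = np.var(dataset.pooled_values(), axis=1)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:lam])


def _run_kmeans(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init="k-means++", n_init=N_RESTARTS, random_state=seed)
    return km.fit(X.T).labels_


def pooled_kmeans(
    dataset: MultiDomainDataset,
    k: int,
    gene_subset: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> list[LabelVector]:
    """k-means on all domains' cells concatenated; labels split back per domain."""
    if sum(dataset.n_cells) < k:
        raise ValueError("fewer cells than clusters")
    X = dataset.pooled_values()
    if gene_subset is not None:
        X = X[np.asarray(gene_subset)]
    labels = _run_kmeans(X, k, seed)
    out, start = [], 0
    for dom in dataset.domains:
        out.append(LabelVector(labels[start : start + dom.n_cells], dom.domain_id))
        start += dom.n_cells
    return out


def separated_kmeans(
    dataset: MultiDomainDataset,
    k: int,
    gene_subset: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> list[LabelVector]:
    """Independent k-means per domain; label spaces are NOT aligned across
    domains."""
    out = []
    for dom in dataset.domains:
        if dom.n_cells < k:
            raise ValueError(f"domain {dom.domain_id!r} has fewer cells than clusters")
        X = dom.values
        if gene_subset is not None:
            X = X[np.asarray(gene_subset)]
        out.append(LabelVector(_run_kmeans(X, k, seed), dom.domain_id))
    return out
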