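"""Synthetic multi-population scRNA-seq generator with planted markers.

The generator emulates the geometry of a multi-population benchmark: cells
from ``k_true`` ground-truth types are separated only inside a small
``n_markers``-dimensional marker subspace; the remaining genes are
label-independent noise. Each population (domain) is then corrupted by a
technical bias — a random small-angle orthogonal rotation mixing the markers
with a few noise genes, per-gene rescaling, and additive noise — so that
pooling the domains misaligns the clusters while the within-domain cluster
structure stays intact. Ground-truth labels, marker indices, and the applied
transforms are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.spatial.distance import pdist

from .data import ExpressionDomain, MultiDomainDataset

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_multidomain", "write_simulation"]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults reproduce the reference scenario: 100 cells split over three
    populations (33, 33, 34) drawn from four cell types, 1000 genes of which
    2 are true markers, with per-domain rotation and rescaling as the
    technical bias.
    """

    D: int = 3
    cells_per_domain: tuple[int, ...] = (33, 33, 34)
    k_true: int = 4
    m_total: int = 1000
    n_markers: int = 2
    cluster_spread: float = 0.4  # within-cluster sd in marker space
    center_scale: float = 13.0  # minimum pairwise distance of true centers
    noise_sd: float = 0.3  # additive noise, all genes
    background_sd: float = 1.0  # sd of the label-independent non-marker genes
    rotate: bool = True
    rotation_angle: float = 0.12  # radians; small-angle technical rotation
    rescale_range: tuple[float, float] = (0.75, 1.3)
    mixing_dims: int = 3  # rotation acts on the first mixing_dims genes
    cluster_proportions: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.cells_per_domain = tuple(self.cells_per_domain)
        if len(self.cells_per_domain) != self.D:
            raise ValueError(
                f"cells_per_domain has {len(self.cells_per_domain)} entries for D={self.D}"
            )
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if not 1 <= self.n_markers < self.m_total:
            raise ValueError("need 1 <= n_markers < m_total")
        if not self.n_markers <= self.mixing_dims <= self.m_total:
            raise ValueError("need n_markers <= mixing_dims <= m_total")
        if self.cluster_spread <= 0 or self.center_scale <= 0:
            raise ValueError("cluster_spread and center_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.rescale_range
        if not (0 < lo <= hi):
            raise ValueError("rescale_range must be 0 < low <= high")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset: per-domain integer labels
    (0-based), the planted marker gene indices, and the per-domain
    (rotation, per-gene scale) transforms."""

    labels: list[np.ndarray]
    marker_indices: np.ndarray
    domain_transforms: list[tuple[Optional[np.ndarray], np.ndarray]] = field(
        default_factory=list
    )


def _true_centers(k: int, dim: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """k cluster centers in marker space with minimum pairwise distance `scale`."""
    while True:
        C = rng.standard_normal((k, dim))
        d = pdist(C) if k > 1 else np.array([1.0])
        if d.min() > 1e-6:
            return C * (scale / d.min())


def _small_rotation(dim: int, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal rotation with largest principal angle = `angle`,
    via the matrix exponential of a normalized skew-symmetric generator."""
    A = rng.standard_normal((dim, dim))
    K = (A - A.T) / 2.0
    nrm = np.linalg.norm(K, 2)
    if nrm == 0:  # dim == 1
        return np.eye(dim)
    return expm(K * (angle / nrm))


def _label_counts(n: int, k: int, proportions: Optional[Sequence[float]]) -> np.ndarray:
    p = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions, float)
    if p.size != k or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("cluster_proportions must be k non-negative values summing to 1")
    # largest-remainder apportionment so every domain realizes the proportions
    raw = p * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def simulate_multidomain(
    config: SimulationConfig,
) -> tuple[MultiDomainDataset, SimulationTruth]:
    """Generate a multi-domain dataset with planted markers.

    Deterministic given ``config.seed``. Values are shifted by one global
    constant so the matrix is non-negative; a shift preserves all cluster
    geometry and every variance in the model.
    """
    rng = np.random.default_rng(config.seed)
    k, m, nm = config.k_true, config.m_total, config.n_markers
    centers = _true_centers(k, nm, config.center_scale, rng)
    marker_idx = np.arange(nm)

    matrices: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    transforms: list[tuple[Optional[np.ndarray], np.ndarray]] = []
    for d, n in enumerate(config.cells_per_domain):
        counts = _label_counts(n, k, config.cluster_proportions)
        lab = rng.permutation(np.repeat(np.arange(k), counts))
        X = np.zeros((m, n))
        X[:nm] = centers[lab].T + config.cluster_spread * rng.standard_normal((nm, n))
        # remaining genes: label-independent variation at the scale typical of
        # (standardized) log-expression, so non-markers are noisy, not constant
        if config.background_sd > 0:
            X[nm:] = config.background_sd * rng.standard_normal((m - nm, n))
        R: Optional[np.ndarray] = None
        if config.rotate and config.mixing_dims > 1:
            R = _small_rotation(config.mixing_dims, config.rotation_angle, rng)
            X[: config.mixing_dims] = R @ X[: config.mixing_dims]
        scales = rng.uniform(*config.rescale_range, size=m)
        X *= scales[:, None]
        if config.noise_sd > 0:
            X += config.noise_sd * rng.standard_normal((m, n))
        matrices.append(X)
        labels.append(lab)
        transforms.append((R, scales))

    shift = min(0.0, min(float(X.min()) for X in matrices))
    gene_ids = [f"gene{i:04d}" for i in range(m)]
    domains = [
        ExpressionDomain(
            domain_id=f"domain{d}",
            values=X - shift,
            cell_ids=[f"domain{d}_cell{c:04d}" for c in range(X.shape[1])],
        )
        for d, X in enumerate(matrices)
    ]
    dataset = MultiDomainDataset(gene_ids, domains)
    truth = SimulationTruth(labels=labels, marker_indices=marker_idx, domain_transforms=transforms)
    return dataset, truth


def write_simulation(
    dataset: MultiDomainDataset,
    truth: SimulationTruth,
    outdir: str | Path,
    fmt: str = "dense-tsv",
) -> list[Path]:
    """Write each domain matrix plus a truth table (cell_id, domain,
    true_label) and the planted marker list. Returns the written paths."""
    from .io import write_domain  # local import to keep module layering flat

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for dom in dataset.domains:
        written.extend(write_domain(dom, outdir / dom.domain_id, dataset.gene_ids, fmt=fmt))
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("cell_id\tdomain\ttrue_label\n")
        for dom, lab in zip(dataset.domains, truth.labels):
            for cid, li in zip(dom.cell_ids, lab):
                fh.write(f"{cid}\t{dom.domain_id}\t{int(li)}\n")
    written.append(truth_path)
    markers_path = outdir / "true_markers.txt"
    with open(markers_path, "w") as fh:
        for i in truth.marker_indices:
            fh.write(dataset.gene_ids[int(i)] + "\n")
    written.append(markers_path)
    return written
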