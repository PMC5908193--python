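"""Readers and writers for expression matrices, results, and run configs.

Two on-disk layouts are supported per domain:

* ``dense-tsv`` — one TSV, header row of cell ids, first column gene ids.
* ``mtx`` — MatrixMarket coordinate file (1-based, per the standard) with
  ``*.genes.tsv`` / ``*.barcodes.tsv`` sidecars, the 10x-style layout. 10x
  files store genes as rows already; ``transpose=True`` handles
  cells-as-rows variants.

Numeric round trips are exact at 17 significant digits.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ExpressionDomain, FitResult, HyperParams, MultiDomainDataset
from .solver import selection_coefficients

__all__ = [
    "read_domain",
    "write_domain",
    "align_gene_index",
    "write_results",
    "load_run_config",
]

logger = logging.getLogger("scvdmc")

FLOAT_FMT = "%.17g"


def _read_ids(path: Path) -> list[str]:
    """Sidecar reader: one identifier per line (first TSV column if tabbed)."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            ids.append(line.split("\t")[0])
    return ids


def read_domain(
    path: str | Path,
    fmt: str = "dense-tsv",
    domain_id: Optional[str] = None,
    genes_path: Optional[str | Path] = None,
    barcodes_path: Optional[str | Path] = None,
    transpose: bool = False,
) -> ExpressionDomain:
    """Read one domain's genes x cells matrix with identifiers attached."""
    path = Path(path)
    if domain_id is None:
        domain_id = path.stem.removesuffix(".matrix")
    if fmt == "dense-tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"malformed dense TSV {path}: {exc}") from exc
        if df.index.has_duplicates:
            raise ValueError(f"{path}: duplicate gene ids")
        if df.columns.has_duplicates:
            raise ValueError(f"{path}: duplicate cell ids")
        values = df.to_numpy(dtype=float)
        if transpose:
            values = values.T
            return ExpressionDomain(
                domain_id, values, [str(c) for c in df.index], [str(g) for g in df.columns]
            )
        return ExpressionDomain(
            domain_id, values, [str(c) for c in df.columns], [str(g) for g in df.index]
        )
    if fmt == "mtx":
        if genes_path is None or barcodes_path is None:
            raise ValueError("mtx format requires genes_path and barcodes_path sidecars")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ValueError(f"malformed MatrixMarket header/body in {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if transpose:
            values = values.T
        genes = _read_ids(Path(genes_path))
        barcodes = _read_ids(Path(barcodes_path))
        if len(genes) != values.shape[0]:
            raise ValueError(
                f"{genes_path}: {len(genes)} gene ids for {values.shape[0]} matrix rows"
            )
        if len(barcodes) != values.shape[1]:
            raise ValueError(
                f"{barcodes_path}: {len(barcodes)} barcodes for {values.shape[1]} columns"
            )
        if len(set(genes)) != len(genes):
            raise ValueError(f"{genes_path}: duplicate gene ids")
        return ExpressionDomain(domain_id, values, barcodes, genes)
    raise ValueError(f"unknown format {fmt!r} (use 'dense-tsv' or 'mtx')")


def write_domain(
    domain: ExpressionDomain,
    prefix: str | Path,
    gene_ids: Optional[Sequence[str]] = None,
    fmt: str = "dense-tsv",
) -> list[Path]:
    """Write one domain under ``prefix``; returns the written paths."""
    gene_ids = list(gene_ids if gene_ids is not None else domain.gene_ids or [])
    if len(gene_ids) != domain.n_genes:
        raise ValueError("gene_ids required and must match the row count")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "dense-tsv":
        out = prefix.with_suffix(".tsv")
        df = pd.DataFrame(domain.values, index=gene_ids, columns=domain.cell_ids)
        df.to_csv(out, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")
        return [out]
    if fmt == "mtx":
        mtx = prefix.with_suffix(".mtx")
        scipy.io.mmwrite(mtx, scipy.sparse.coo_matrix(domain.values), precision=17)
        gpath = prefix.with_suffix(".genes.tsv")
        gpath.write_text("".join(g + "\n" for g in gene_ids))
        bpath = prefix.with_suffix(".barcodes.tsv")
        bpath.write_text("".join(c + "\n" for c in domain.cell_ids))
        return [mtx, gpath, bpath]
    raise ValueError(f"unknown format {fmt!r}")


def align_gene_index(domains: Sequence[ExpressionDomain]) -> MultiDomainDataset:
    """Intersect per-domain gene indices into one shared, sorted order.

    Every domain matrix is reordered to the intersection; dropped genes are
    logged per domain. Raises when the intersection is empty.
    """
    if len(domains) < 1:
        raise ValueError("need at least one domain")
    for dom in domains:
        if dom.gene_ids is None:
            raise ValueError(f"domain {dom.domain_id!r} carries no gene ids")
    shared = set(domains[0].gene_ids)
    for dom in domains[1:]:
        shared &= set(dom.gene_ids)
    if not shared:
        raise ValueError("gene-index intersection across domains is empty")
    order = sorted(shared)
    aligned = []
    for dom in domains:
        dropped = len(dom.gene_ids) - len(order)
        if dropped:
            logger.info("align_gene_index: dropping %d genes from %s", dropped, dom.domain_id)
        pos = {g: i for i, g in enumerate(dom.gene_ids)}
        idx = np.array([pos[g] for g in order])
        aligned.append(ExpressionDomain(dom.domain_id, dom.values[idx], list(dom.cell_ids)))
    return MultiDomainDataset(order, aligned)


def write_results(
    result: FitResult,
    dataset: MultiDomainDataset,
    params: HyperParams,
    outdir: str | Path,
) -> dict:
    """Write assignments, ranked markers, centers, the objective trace, and a
    JSON run report; returns the manifest (name -> path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for dom, labels in zip(dataset.domains, result.labels):
        p = outdir / f"assignments_{dom.domain_id}.tsv"
        pd.DataFrame({"cell_id": dom.cell_ids, "cluster": labels}).to_csv(
            p, sep="\t", index=False
        )
        manifest[f"assignments_{dom.domain_id}"] = str(p)

    coeff = selection_coefficients(dataset, result.U, result.V, params.w, params.alpha)
    sel = np.flatnonzero(result.B)
    ranked = sel[np.argsort(coeff[sel], kind="stable")]
    p = outdir / "markers.tsv"
    pd.DataFrame(
        {
            "gene_id": [dataset.gene_ids[i] for i in ranked],
            "selection_coefficient": coeff[ranked],
            "rank": np.arange(1, ranked.size + 1),
        }
    ).to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
    manifest["markers"] = str(p)

    for dom, Ud in zip(dataset.domains, result.U):
        p = outdir / f"centers_{dom.domain_id}.tsv"
        pd.DataFrame(
            Ud, index=dataset.gene_ids, columns=[f"cluster{j}" for j in range(Ud.shape[1])]
        ).to_csv(p, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")
        manifest[f"centers_{dom.domain_id}"] = str(p)

    p = outdir / "objective_trace.tsv"
    pd.DataFrame(
        {"iteration": np.arange(1, len(result.objective_trace) + 1),
         "objective": result.objective_trace}
    ).to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
    manifest["objective_trace"] = str(p)

    report = {
        "hyperparameters": {
            "k": params.k, "lam": params.lam, "w": params.w, "alpha": params.alpha,
            "max_iter": params.max_iter, "tol": params.tol, "seed": params.seed,
        },
        "n_domains": dataset.n_domains,
        "n_genes": dataset.n_genes,
        "n_cells": dataset.n_cells,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "versions": {"python": platform.python_version(), "numpy": np.__version__},
        "files": manifest,
    }
    p = outdir / "run_report.json"
    p.write_text(json.dumps(report, indent=2))
    manifest["run_report"] = str(p)
    return manifest


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration (flat keys mirroring the CLI flags)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
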