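"""Clustering evaluation: best one-to-one matching error and adjusted Rand index."""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = ["clustering_error", "adjusted_rand_index", "contingency", "evaluation_report"]

Labels = Union[np.ndarray, Sequence[int]]


def _labels(x) -> np.ndarray:
    # accept bare arrays/lists or LabelVector-like objects
    if hasattr(x, "labels"):
        x = x.labels
    return np.asarray(x)


def contingency(pred: Labels, truth: Labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contingency table plus the distinct predicted / true labels."""
    pred, truth = _labels(pred), _labels(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"label vectors differ in length: {pred.size} vs {truth.size}")
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    C = np.zeros((pu.size, tu.size), dtype=int)
    np.add.at(C, (pi, ti), 1)
    return C, pu, tu


def clustering_error(pred: Labels, truth: Labels) -> float:
    """Misclassification fraction under the best one-to-one cluster matching.

    Predicted clusters are optimally paired with true clusters by maximizing
    the total overlap of the contingency table (Hungarian algorithm on the
    possibly rectangular table; clusters without a partner contribute all
    their cells as errors). Invariant to relabeling of either side and
    symmetric in its arguments.
    """
    C, _, _ = contingency(pred, truth)
    r, c = linear_sum_assignment(-C)
    matched = C[r, c].sum()
    return 1.0 - matched / C.sum()


def adjusted_rand_index(pred: Labels, truth: Labels) -> float:
    """Hubert-Arabie adjusted Rand index: 1 for identical partitions, 0 in
    expectation for independent ones."""
    pred, truth = _labels(pred), _labels(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"label vectors differ in length: {pred.size} vs {truth.size}")
    if pred.size < 2:
        raise ValueError("need at least two cells")
    return float(adjusted_rand_score(truth, pred))


def evaluation_report(
    preds: Sequence[Labels], truths: Sequence[Labels], domain_ids: Sequence[str] | None = None
) -> dict:
    """Per-domain and pooled evaluation of a multi-domain clustering.

    Matching ambiguity is reported both ways: ``error`` matches clusters
    globally on the concatenated labels, ``per_domain`` matches within each
    domain separately.
    """
    if len(preds) != len(truths):
        raise ValueError("one prediction per truth vector required")
    if domain_ids is None:
        domain_ids = [f"domain{d}" for d in range(len(preds))]
    per_domain = {}
    for did, p, t in zip(domain_ids, preds, truths):
        per_domain[did] = {
            "error": clustering_error(p, t),
            "ari": adjusted_rand_index(p, t),
            "n_cells": int(_labels(p).size),
        }
    pooled_pred = np.concatenate([_labels(p) for p in preds])
    pooled_truth = np.concatenate([_labels(t) for t in truths])
    return {
        "per_domain": per_domain,
        "pooled": {
            "error": clustering_error(pooled_pred, pooled_truth),
            "ari": adjusted_rand_index(pooled_pred, pooled_truth),
            "n_cells": int(pooled_pred.size),
        },
    }
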