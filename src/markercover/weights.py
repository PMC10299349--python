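"""Per-class expression probabilities, gene weights, and candidate filtering.

The discriminativeness weight of gene g for class k compares its expression
probability outside the class to that inside the class; genes with weight
<= 1 and in-class expression probability >= ``min_expr`` form the candidate
set handed to the covering solver.

Weight schemes
--------------
``mean_ratio``      off-class probabilities averaged over the K-1 other
                    classes, divided by the in-class probability (default).
``max_ratio``       maximum off-class probability divided by in-class.
``lognorm_ratio``   mean_ratio computed on per-class means of log-normalized
                    expression instead of binary probabilities.
``bonferroni``      pooled off-class expression probability
                    P(expressed | class != k), cell-weighted.
``log_complement``  -log(1 - pooled off-class probability).

Division by zero yields +inf, which can never enter a candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import BinaryMatrix, ExpressionMatrix

SCHEMES = ("mean_ratio", "max_ratio", "lognorm_ratio", "bonferroni", "log_complement")

DEFAULT_MIN_EXPR = 0.1
DEFAULT_MAX_WEIGHT = 1.0


@dataclass
class ClassProbabilities:
    """Empirical per-(gene, class) expression probabilities on binarized data."""

    m: np.ndarray               # genes x classes, values in [0, 1]
    classes: list
    class_sizes: np.ndarray     # cells per class
    gene_ids: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.min() < 0 or self.m.max() > 1 + 1e-12:
            raise DataError("probabilities must lie in [0, 1]")
        if self.m.shape != (len(self.gene_ids), len(self.classes)):
            raise DataError("probability matrix shape does not match metadata")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def column(self, class_name) -> np.ndarray:
        return self.m[:, self.classes.index(class_name)]


@dataclass
class ClassMeans:
    """Per-(gene, class) means of log-normalized expression (non-negative reals)."""

    m: np.ndarray
    classes: list
    class_sizes: np.ndarray
    gene_ids: np.ndarray
    target_sum: float = 1e4
    log_base: float = float(np.e)


def _check_labels(b, labels):
    if labels is None:
        labels = b.labels
    if labels is None:
        raise DataError("no labels given and matrix carries none")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != b.n_cells:
        raise DataError(f"{len(labels)} labels for {b.n_cells} cells")
    classes = sorted(set(labels))
    if len(classes) < 1:
        raise DataError("at least one class required")
    return labels, classes


def estimate_probabilities(b: BinaryMatrix, labels=None) -> ClassProbabilities:
    """m(g, k) = fraction of class-k cells in which gene g is detected."""
    labels, classes = _check_labels(b, labels)
    G = b.n_genes
    m = np.zeros((G, len(classes)))
    sizes = np.zeros(len(classes), dtype=int)
    ind = b.indicator
    for j, k in enumerate(classes):
        cols = np.flatnonzero(labels == k)
        if cols.size == 0:
            raise DataError(f"class {k!r} is empty")
        sizes[j] = cols.size
        m[:, j] = np.asarray(ind[:, cols].sum(axis=1)).ravel() / cols.size
    return ClassProbabilities(
        m=m, classes=classes, class_sizes=sizes, gene_ids=b.gene_ids
    )


def lognormalize(counts, target_sum: float = 1e4, log_base: float = np.e) -> np.ndarray:
    """Depth-normalize each cell to ``target_sum`` total counts, then log(1 + x).

    Cells with zero total counts stay all-zero. Returns a dense array.
    """
    X = np.asarray(counts.todense() if hasattr(counts, "todense") else counts,
                   dtype=float)
    depth = X.sum(axis=0)
    scale = np.divide(target_sum, depth, out=np.zeros_like(depth), where=depth > 0)
    out = np.log1p(X * scale[np.newaxis, :])
    if log_base != np.e:
        out /= np.log(log_base)
    return out


def estimate_mean_lognorm(
    m: ExpressionMatrix,
    labels=None,
    target_sum: float = 1e4,
    log_base: float = np.e,
) -> ClassMeans:
    """Per-class means of log-normalized expression, for the lognorm weight scheme."""
    labels, classes = _check_labels(m, labels)
    X = lognormalize(m.counts, target_sum=target_sum, log_base=log_base)
    means = np.zeros((m.n_genes, len(classes)))
    sizes = np.zeros(len(classes), dtype=int)
    for j, k in enumerate(classes):
        cols = np.flatnonzero(labels == k)
        if cols.size == 0:
            raise DataError(f"class {k!r} is empty")
        sizes[j] = cols.size
        means[:, j] = X[:, cols].mean(axis=1)
    return ClassMeans(
        m=means, classes=classes, class_sizes=sizes, gene_ids=m.gene_ids,
        target_sum=target_sum, log_base=log_base,
    )


@dataclass
class WeightTable:
    """Gene weights per class under one scheme; lower = more class-specific."""

    w: np.ndarray               # genes x classes, non-negative, may be +inf
    scheme: str
    classes: list
    gene_ids: np.ndarray

    def column(self, class_name) -> np.ndarray:
        return self.w[:, self.classes.index(class_name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.gene_ids, columns=self.classes)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.inf, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        np.divide(num, den, out=out, where=den > 0)
    out[(num == 0) & (den > 0)] = 0.0
    return out


def compute_weights(
    probs: ClassProbabilities,
    scheme: str = "mean_ratio",
    means: Optional[ClassMeans] = None,
) -> WeightTable:
    """Compute the weight of every gene for every class under ``scheme``.

    ``means`` (per-class log-normalized means) is required for
    ``lognorm_ratio`` and ignored otherwise.
    """
    if scheme not in SCHEMES:
        raise DataError(f"unknown weight scheme {scheme!r}; choose from {SCHEMES}")
    K = probs.n_classes
    if K < 2:
        raise DataError(f"weights require at least 2 classes, got {K}")

    if scheme == "lognorm_ratio":
        if means is None:
            raise DataError("lognorm_ratio requires per-class log-normalized means")
        M = np.asarray(means.m, dtype=float)
    else:
        M = probs.m
    G = M.shape[0]
    w = np.zeros((G, K))
    sizes = np.asarray(probs.class_sizes, dtype=float)

    for j in range(K):
        others = np.delete(np.arange(K), j)
        if scheme in ("mean_ratio", "lognorm_ratio"):
            off = M[:, others].sum(axis=1) / (K - 1)
            w[:, j] = _safe_ratio(off, M[:, j])
        elif scheme == "max_ratio":
            off = M[:, others].max(axis=1)
            w[:, j] = _safe_ratio(off, M[:, j])
        else:
            # pooled off-class probability, cell-weighted over all non-k cells
            pooled = (probs.m[:, others] * sizes[others]).sum(axis=1) / sizes[others].sum()
            if scheme == "bonferroni":
                w[:, j] = pooled
            else:  # log_complement
                with np.errstate(divide="ignore"):
                    w[:, j] = -np.log1p(-np.clip(pooled, 0.0, 1.0))
    return WeightTable(w=w, scheme=scheme, classes=list(probs.classes),
                       gene_ids=probs.gene_ids)


def candidate_set(
    weights: WeightTable,
    probs: ClassProbabilities,
    class_name,
    min_expr: float = DEFAULT_MIN_EXPR,
    max_weight: float = DEFAULT_MAX_WEIGHT,
) -> np.ndarray:
    """Boolean gene mask: weight <= max_weight and in-class probability >= min_expr.

    The probability filter always uses the binarized probabilities, whatever
    the weight scheme. An empty result is legal; downstream reports
    infeasibility.
    """
    if list(weights.gene_ids) != list(probs.gene_ids):
        raise DataError("weights and probabilities index different genes")
    w = weights.column(class_name)
    m = probs.column(class_name)
    return (w <= max_weight) & (m >= min_expr)


def weights_to_table(
    weights: WeightTable,
    probs: ClassProbabilities,
    min_expr: float = DEFAULT_MIN_EXPR,
    max_weight: float = DEFAULT_MAX_WEIGHT,
) -> pd.DataFrame:
    """Flat export: one row per (gene, class) with m, w and the candidate flag."""
    rows = []
    for k in weights.classes:
        cand = candidate_set(weights, probs, k, min_expr, max_weight)
        w = weights.column(k)
        m = probs.column(k)
        for i, g in enumerate(weights.gene_ids):
            rows.append({"gene": g, "class": k, "m": m[i], "w": w[i],
                         "candidate": bool(cand[i])})
    return pd.DataFrame(rows, columns=["gene", "class", "m", "w", "candidate"])
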