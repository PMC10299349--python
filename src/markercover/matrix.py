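"""Expression matrices (genes x cells) and their binarized views."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .errors import DataError


def _as_str_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional")
    arr = np.array([str(v) for v in arr], dtype=object)
    if len(set(arr)) != len(arr):
        dupes = sorted({v for v in arr if list(arr).count(v) > 1})
        raise DataError(f"duplicate {name}: {dupes[:5]}")
    return arr


@dataclass
class ExpressionMatrix:
    """Non-negative counts indexed by (gene, cell), with optional class labels.

    ``counts`` is stored genes x cells as a CSR sparse matrix. ``labels``, if
    present, is an object array aligned with ``cell_ids`` (one class name per
    cell).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts, dtype=float))
        else:
            self.counts = self.counts.tocsr().astype(float)
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        ng, nc = self.counts.shape
        if ng != len(self.gene_ids):
            raise DataError(
                f"counts has {ng} gene rows but {len(self.gene_ids)} gene_ids"
            )
        if nc != len(self.cell_ids):
            raise DataError(
                f"counts has {nc} cell columns but {len(self.cell_ids)} cell_ids"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("counts must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(
                [None if v is None else str(v) for v in self.labels], dtype=object
            )
            if len(self.labels) != nc:
                raise DataError(
                    f"{len(self.labels)} labels for {nc} cells"
                )
            missing = [
                cid for cid, lab in zip(self.cell_ids, self.labels)
                if lab is None or lab == "" or lab == "nan"
            ]
            if missing:
                raise DataError(f"cells without a label: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def classes(self) -> list:
        """Sorted unique class names (requires labels)."""
        if self.labels is None:
            raise DataError("matrix has no labels")
        return sorted(set(self.labels))

    def class_indices(self, class_name: str) -> np.ndarray:
        """Column indices of the cells belonging to ``class_name``."""
        if self.labels is None:
            raise DataError("matrix has no labels")
        idx = np.flatnonzero(self.labels == class_name)
        if idx.size == 0:
            raise DataError(f"class {class_name!r} has no cells")
        return idx

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class BinaryMatrix:
    """Binarized view: indicator(g, c) = 1 iff counts(g, c) > theta."""

    indicator: sp.csr_matrix
    theta: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: Optional[np.ndarray] = None
    source: Optional[ExpressionMatrix] = field(default=None, repr=False)

    def __post_init__(self):
        if not sp.issparse(self.indicator):
            self.indicator = sp.csr_matrix(np.asarray(self.indicator))
        self.indicator = self.indicator.tocsr().astype(np.int8)
        if self.indicator.nnz:
            vals = np.unique(self.indicator.data)
            if not set(vals.tolist()) <= {0, 1}:
                raise DataError("indicator entries must be 0/1")

    @property
    def n_genes(self) -> int:
        return self.indicator.shape[0]

    @property
    def n_cells(self) -> int:
        return self.indicator.shape[1]

    @property
    def classes(self) -> list:
        if self.labels is None:
            raise DataError("matrix has no labels")
        return sorted(set(self.labels))

    def class_indices(self, class_name: str) -> np.ndarray:
        if self.labels is None:
            raise DataError("matrix has no labels")
        idx = np.flatnonzero(self.labels == class_name)
        if idx.size == 0:
            raise DataError(f"class {class_name!r} has no cells")
        return idx

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


def binarize(m, theta: float = 0.0) -> BinaryMatrix:
    """Binarize counts with a strict threshold: expressed iff count > theta.

    With raw integer counts and the default theta = 0 this is exactly
    "detected at count >= 1". Accepts an :class:`ExpressionMatrix` or an
    existing :class:`BinaryMatrix` (idempotent at theta = 0).
    """
    if theta < 0:
        raise DataError(f"theta must be >= 0, got {theta}")
    if isinstance(m, BinaryMatrix):
        src = m.indicator
        indicator = (src > theta).astype(np.int8)
        return BinaryMatrix(
            indicator=indicator, theta=m.theta, gene_ids=m.gene_ids,
            cell_ids=m.cell_ids, labels=m.labels, source=m.source,
        )
    indicator = (m.counts > theta).astype(np.int8)
    return BinaryMatrix(
        indicator=indicator, theta=float(theta), gene_ids=m.gene_ids,
        cell_ids=m.cell_ids, labels=m.labels, source=m,
    )
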