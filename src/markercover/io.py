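"""Readers and writers for expression matrices and panel files.

Matrix formats
--------------
* ``mtx``: Matrix Market coordinate file plus two tab-separated metadata
  files — ``genes.tsv`` (first column = gene ID) and ``cells.tsv`` (first
  column = cell ID, optional label column). Header rows are mandatory.
* ``csv``: dense CSV with genes as rows; the first column holds gene IDs and
  the header row holds cell IDs.

Orientation is never guessed: matrices are stored genes x cells and callers
must pass ``orientation="cells_by_genes"`` explicitly to transpose on read.

Panel files are JSON with an explicit ``schema_version``; a flat TSV
(class, gene, weight, rank) is written alongside for spreadsheet use.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DataError
from .matrix import ExpressionMatrix
from .panels import MarkerPanel, PanelSet

PANEL_SCHEMA_VERSION = 1


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with file name
        raise DataError(f"cannot parse TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"{path} has no columns")
    return df


def read_matrix(
    counts_path,
    genes_path=None,
    cells_path=None,
    fmt: Optional[str] = None,
    label_col: Optional[str] = None,
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    counts_path : path to the .mtx or .csv counts file.
    genes_path, cells_path : metadata TSVs, required for ``fmt="mtx"``;
        ``cells_path`` is optional for ``fmt="csv"`` (labels only).
    fmt : "mtx" or "csv"; inferred from the counts file suffix if omitted.
    label_col : name of the label column in ``cells.tsv`` to attach.
    orientation : "genes_by_cells" (default) or "cells_by_genes".
    """
    counts_path = Path(counts_path)
    if not counts_path.exists():
        raise DataError(f"counts file not found: {counts_path}")
    if fmt is None:
        suffix = counts_path.suffix.lower()
        fmt = {"mtx": "mtx", ".mtx": "mtx", ".csv": "csv"}.get(suffix)
        if fmt is None:
            raise DataError(
                f"cannot infer format from suffix {suffix!r}; pass fmt explicitly"
            )
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise DataError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise DataError("mtx format requires genes_path and cells_path")
        try:
            counts = sp.csr_matrix(scipy.io.mmread(str(counts_path)))
        except Exception as exc:  # noqa: BLE001
            raise DataError(f"cannot parse Matrix Market file {counts_path}: {exc}") from exc
        genes_df = _read_tsv(genes_path)
        cells_df = _read_tsv(cells_path)
        if orientation == "cells_by_genes":
            counts = counts.T.tocsr()
        gene_ids = genes_df.iloc[:, 0].to_numpy(dtype=object)
        cell_ids = cells_df.iloc[:, 0].to_numpy(dtype=object)
        if counts.shape[0] != len(gene_ids):
            raise DataError(
                f"{counts_path} has {counts.shape[0]} gene rows but "
                f"{genes_path} lists {len(gene_ids)} genes"
            )
        if counts.shape[1] != len(cell_ids):
            raise DataError(
                f"{counts_path} has {counts.shape[1]} cell columns but "
                f"{cells_path} lists {len(cell_ids)} cells"
            )
        labels = _extract_labels(cells_df, label_col, cells_path)
    elif fmt == "csv":
        try:
            df = pd.read_csv(counts_path, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise DataError(f"cannot parse CSV {counts_path}: {exc}") from exc
        if orientation == "cells_by_genes":
            df = df.T
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
        counts = sp.csr_matrix(df.to_numpy(dtype=float))
        labels = None
        if cells_path is not None:
            cells_df = _read_tsv(cells_path)
            if len(cells_df) != len(cell_ids):
                raise DataError(
                    f"{cells_path} lists {len(cells_df)} cells but "
                    f"{counts_path} has {len(cell_ids)}"
                )
            labels = _extract_labels(cells_df, label_col, cells_path)
        elif label_col is not None:
            raise DataError("label_col given but no cells_path to read it from")
    else:
        raise DataError(f"unknown format {fmt!r}")

    return ExpressionMatrix(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, labels=labels
    )


def _extract_labels(cells_df: pd.DataFrame, label_col, path) -> Optional[np.ndarray]:
    if label_col is None:
        return None
    if label_col not in cells_df.columns:
        raise DataError(
            f"label column {label_col!r} not found in {path} "
            f"(columns: {list(cells_df.columns)})"
        )
    labels = cells_df[label_col].to_numpy(dtype=object)
    if pd.isna(labels).any():
        raise DataError(f"label column {label_col!r} in {path} has missing values")
    return labels


def write_matrix(m: ExpressionMatrix, prefix, label_col: str = "label") -> dict:
    """Write ``<prefix>.mtx`` + ``<prefix>.genes.tsv`` + ``<prefix>.cells.tsv``.

    Returns the paths written, keyed by role.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx_path = prefix.with_suffix(prefix.suffix + ".mtx")
    genes_path = prefix.with_suffix(prefix.suffix + ".genes.tsv")
    cells_path = prefix.with_suffix(prefix.suffix + ".cells.tsv")
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(m.counts))
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": m.cell_ids})
    if m.labels is not None:
        cells[label_col] = m.labels
    cells.to_csv(cells_path, sep="\t", index=False)
    return {"counts": mtx_path, "genes": genes_path, "cells": cells_path}


def write_panels(ps: PanelSet, path, tsv_path=None) -> dict:
    """Serialize a panel set to JSON (full precision) and a companion TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema_version": PANEL_SCHEMA_VERSION,
        "panels": [p.to_dict() for p in ps],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    if tsv_path is None:
        tsv_path = path.with_suffix(".tsv")
    panels_to_tsv(ps).to_csv(tsv_path, sep="\t", index=False)
    return {"json": path, "tsv": Path(tsv_path)}


def panels_to_tsv(ps: PanelSet) -> pd.DataFrame:
    rows = []
    for p in ps:
        for rank, (g, w) in enumerate(zip(p.genes, p.weights), start=1):
            rows.append({"class": p.class_name, "gene": g, "weight": w, "rank": rank})
    return pd.DataFrame(rows, columns=["class", "gene", "weight", "rank"])


def read_panels(path) -> PanelSet:
    path = Path(path)
    if not path.exists():
        raise DataError(f"panel file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"cannot parse panel JSON {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != PANEL_SCHEMA_VERSION:
        raise DataError(
            f"unsupported panel schema version {version!r} in {path} "
            f"(expected {PANEL_SCHEMA_VERSION})"
        )
    panels = {}
    for d in payload.get("panels", []):
        p = MarkerPanel.from_dict(d)
        panels[p.class_name] = p
    return PanelSet(panels=panels)
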