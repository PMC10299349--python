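"""Apply fitted panels to new datasets.

Panel genes absent from the target namespace are dropped from numerators,
denominators and sums alike; ``panel_genes_found`` is always reported so the
shrinkage is visible. Gene matching is exact-string; ortholog mapping is the
caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import BinaryMatrix, ExpressionMatrix


def _match_panel(panel_genes, target_gene_ids):
    """Dedupe panel genes (order-preserving) and locate them in the target."""
    seen = set()
    genes = []
    for g in panel_genes:
        g = str(g)
        if g not in seen:
            seen.add(g)
            genes.append(g)
    pos = {g: i for i, g in enumerate(target_gene_ids)}
    found = [g for g in genes if g in pos]
    missing = [g for g in genes if g not in pos]
    return [pos[g] for g in found], found, missing


@dataclass
class TransferResult:
    """Per-cell or per-class panel activity in a target dataset."""

    mode: str                      # proportion | rate_at_depth | bulk_sum
    values: pd.Series              # indexed by cell/sample/class
    panel_genes_found: int
    missing_genes: List[str]
    depth: Optional[int] = None
    strict_greater: bool = False


def panel_depths(panel_genes, target: BinaryMatrix) -> TransferResult:
    """Integer count of panel genes expressed per target cell."""
    rows, found, missing = _match_panel(panel_genes, target.gene_ids)
    if not rows:
        raise DataError(
            f"no panel gene present in target; missing: {sorted(missing)}"
        )
    depths = np.asarray(target.indicator[rows, :].sum(axis=0)).ravel()
    return TransferResult(
        mode="depth",
        values=pd.Series(depths, index=list(target.cell_ids), name="depth"),
        panel_genes_found=len(found),
        missing_genes=missing,
    )


def depth_classifier(panel_genes, depth: int, target: BinaryMatrix) -> np.ndarray:
    """Binary per-cell call: 1 iff the cell expresses >= depth panel genes.

    Only panel genes present in the target count; depth 0 is vacuously 1.
    """
    if depth <= 0:
        return np.ones(target.n_cells, dtype=np.int8)
    res = panel_depths(panel_genes, target)
    return (res.values.to_numpy() >= depth).astype(np.int8)


def cell_proportions(panel_genes, target: BinaryMatrix) -> TransferResult:
    """Per cell: expressed panel genes / panel genes present in the target."""
    res = panel_depths(panel_genes, target)
    props = res.values / res.panel_genes_found
    return TransferResult(
        mode="proportion",
        values=props.rename("proportion"),
        panel_genes_found=res.panel_genes_found,
        missing_genes=res.missing_genes,
    )


def class_covering_rates(
    panel_genes,
    target: BinaryMatrix,
    depth: int,
    labels=None,
    strict_greater: bool = False,
) -> TransferResult:
    """Fraction of each target class's cells expressing >= depth panel genes.

    ``strict_greater=True`` switches the comparison to > depth (the "more
    than d markers" convention used in some figure-level summaries).
    """
    if labels is None:
        labels = target.labels
    if labels is None:
        raise DataError("target labels are required for class covering rates")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != target.n_cells:
        raise DataError(f"{len(labels)} labels for {target.n_cells} cells")
    res = panel_depths(panel_genes, target)
    depths = res.values.to_numpy()
    hits = (depths > depth) if strict_greater else (depths >= depth)
    classes = sorted(set(labels))
    rates = {}
    for k in classes:
        idx = labels == k
        rates[k] = float(np.mean(hits[idx]))
    return TransferResult(
        mode="rate_at_depth",
        values=pd.Series(rates, name="covering_rate"),
        panel_genes_found=res.panel_genes_found,
        missing_genes=res.missing_genes,
        depth=depth,
        strict_greater=strict_greater,
    )


def bulk_transfer(panel_genes, target: ExpressionMatrix) -> TransferResult:
    """Per-sample panel score for bulk data.

    Sum of panel gene expression in each sample, divided by the maximum sum
    across samples — the top sample scores exactly 1.
    """
    rows, found, missing = _match_panel(panel_genes, target.gene_ids)
    if not rows:
        raise DataError(
            f"no panel gene present in target; missing: {sorted(missing)}"
        )
    sums = np.asarray(target.counts[rows, :].sum(axis=0)).ravel()
    top = sums.max()
    if top <= 0:
        raise DataError("every sample has zero total panel expression")
    return TransferResult(
        mode="bulk_sum",
        values=pd.Series(sums / top, index=list(target.cell_ids), name="score"),
        panel_genes_found=len(found),
        missing_genes=missing,
    )


def transfer_panelset(
    ps,
    target: BinaryMatrix,
    mode: str,
    depth: int = 1,
    labels=None,
    strict_greater: bool = False,
) -> pd.DataFrame:
    """Run one transfer mode for every panel in a set; long-format table."""
    rows = []
    for panel in ps:
        if not panel.genes:
            continue
        if mode == "proportion":
            res = cell_proportions(panel.genes, target)
            unit = "cell"
        elif mode == "rate":
            res = class_covering_rates(
                panel.genes, target, depth, labels=labels,
                strict_greater=strict_greater,
            )
            unit = "target_class"
        elif mode == "bulk":
            res = bulk_transfer(panel.genes, target)
            unit = "sample"
        else:
            raise DataError(f"unknown transfer mode {mode!r}")
        for key, val in res.values.items():
            rows.append({
                "panel_class": panel.class_name,
                unit: key,
                "value": float(val),
                "panel_genes_found": res.panel_genes_found,
            })
    return pd.DataFrame(rows)
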