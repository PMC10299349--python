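"""Cross-dataset cell-type mapping via 0-1 normalized covering rates.

For every source class panel, compute the fraction of each target class's
cells expressing at least ``depth`` of its markers, min-max normalize those
rates across target classes, and map the source class to every target class
whose normalized rate strictly exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import BinaryMatrix
from .panels import PanelSet
from .transfer import class_covering_rates

logger = logging.getLogger(__name__)

DEFAULT_DEPTH = 5
DEFAULT_THRESHOLD = 0.8


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """0-1 normalize; returns all-NaN when the values are constant."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, np.nan)
    return (values - lo) / (hi - lo)


@dataclass
class MappingResult:
    raw: pd.DataFrame           # source classes x target classes
    normalized: pd.DataFrame    # same shape; NaN rows where normalization degenerates
    mapped: Set[Tuple[str, str]]
    depth: int
    threshold: float
    degenerate: List[str] = field(default_factory=list)   # all-equal raw rates
    depth_adjusted: Dict[str, int] = field(default_factory=dict)


def map_cell_types(
    ps: PanelSet,
    target: BinaryMatrix,
    depth: int = DEFAULT_DEPTH,
    threshold: float = DEFAULT_THRESHOLD,
    labels=None,
) -> MappingResult:
    """Map each source class to target classes by normalized covering rate.

    A source panel smaller than ``depth`` has its depth lowered to the panel
    size (logged). A source class whose raw rates are constant across target
    classes cannot be normalized and is reported unmapped.
    """
    if depth < 1:
        raise DataError(f"depth must be >= 1, got {depth}")
    if not (0.0 < threshold < 1.0):
        raise DataError(f"threshold must be in (0, 1), got {threshold}")
    if labels is None:
        labels = target.labels
    if labels is None:
        raise DataError("target labels are required for cell-type mapping")

    raw_rows = {}
    depth_adjusted = {}
    for panel in ps:
        if not panel.genes:
            continue
        d = depth
        if len(panel.genes) < depth:
            d = len(panel.genes)
            depth_adjusted[panel.class_name] = d
            logger.warning(
                "panel %s has %d genes < depth %d; using depth %d",
                panel.class_name, len(panel.genes), depth, d,
            )
        res = class_covering_rates(panel.genes, target, d, labels=labels)
        raw_rows[panel.class_name] = res.values
    if not raw_rows:
        raise DataError("panel set has no non-empty panels")

    raw = pd.DataFrame(raw_rows).T
    raw = raw.reindex(sorted(raw.index))[sorted(raw.columns)]

    normalized = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    degenerate = []
    mapped = set()
    for k in raw.index:
        row = raw.loc[k].to_numpy(dtype=float)
        norm = minmax_normalize(row)
        if np.isnan(norm).all():
            degenerate.append(k)
            logger.warning(
                "source class %s: covering rates constant across target "
                "classes; left unmapped", k,
            )
            continue
        normalized.loc[k] = norm
        for kp, val in zip(raw.columns, norm):
            if val > threshold:
                mapped.add((k, kp))
    return MappingResult(
        raw=raw, normalized=normalized, mapped=mapped, depth=depth,
        threshold=threshold, degenerate=degenerate, depth_adjusted=depth_adjusted,
    )


def mapping_table(mr: MappingResult) -> pd.DataFrame:
    """One row per (source, target) pair in deterministic sorted order."""
    rows = []
    for k in mr.raw.index:
        for kp in mr.raw.columns:
            norm = mr.normalized.loc[k, kp]
            rows.append({
                "source_class": k,
                "target_class": kp,
                "raw_rate": float(mr.raw.loc[k, kp]),
                "normalized_rate": float(norm) if pd.notna(norm) else float("nan"),
                "mapped": (k, kp) in mr.mapped,
            })
    return pd.DataFrame(
        rows,
        columns=["source_class", "target_class", "raw_rate",
                 "normalized_rate", "mapped"],
    )
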