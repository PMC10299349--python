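"""Panel-quality metrics: redundancy, intersection, balanced accuracy, and a
transparent frequency-difference reference ranking for size-matched baselines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .errors import DataError
from .panels import PanelSet
from .weights import ClassProbabilities


def redundancy(ps: PanelSet) -> float:
    """Fraction of the global panel's genes appearing in >= 2 class panels."""
    gene_count = {}
    for panel in ps:
        for g in set(panel.genes):
            gene_count[g] = gene_count.get(g, 0) + 1
    if not gene_count:
        raise DataError("all panels are empty; redundancy undefined")
    shared = sum(1 for c in gene_count.values() if c >= 2)
    return shared / len(gene_count)


def panel_intersection(candidate_genes, reference_genes) -> float:
    """|candidate ∩ reference| / |reference|."""
    ref = set(map(str, reference_genes))
    if not ref:
        raise DataError("reference panel is empty; intersection undefined")
    cand = set(map(str, candidate_genes))
    return len(cand & ref) / len(ref)


@dataclass
class ConfusionSummary:
    classes: List[str]
    counts: pd.DataFrame            # true x predicted
    recalls: pd.Series              # per true class with support
    zero_support: List[str] = field(default_factory=list)

    @property
    def balanced_accuracy(self) -> float:
        return float(self.recalls.mean())


def confusion_summary(y_true, y_pred) -> ConfusionSummary:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise DataError(
            f"label vectors differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    if len(y_true) == 0:
        raise DataError("empty label vectors")
    classes = sorted(set(y_true) | set(y_pred))
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        counts.loc[t, p] += 1
    support = counts.sum(axis=1)
    zero_support = [k for k in classes if support[k] == 0]
    with_support = [k for k in classes if support[k] > 0]
    if not with_support:
        raise DataError("no class has support")
    recalls = pd.Series(
        {k: counts.loc[k, k] / support[k] for k in with_support}, name="recall"
    )
    return ConfusionSummary(
        classes=classes, counts=counts, recalls=recalls, zero_support=zero_support
    )


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall over classes with support in ``y_true``."""
    return confusion_summary(y_true, y_pred).balanced_accuracy


def frequency_rank_reference(probs: ClassProbabilities, class_name, n: int):
    """Top-n genes by in-class minus best off-class expression frequency.

    A deliberately simple one-gene-at-a-time ranking used as a size-matched
    baseline in redundancy comparisons. Ties break by gene ID for
    determinism.
    """
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    G = len(probs.gene_ids)
    if n > G:
        raise DataError(f"requested top {n} of only {G} genes")
    j = probs.classes.index(class_name)
    others = np.delete(np.arange(probs.n_classes), j)
    score = probs.m[:, j] - probs.m[:, others].max(axis=1)
    order = sorted(range(G), key=lambda i: (-score[i], str(probs.gene_ids[i])))
    return [str(probs.gene_ids[i]) for i in order[:n]]


def reference_panelset(probs: ClassProbabilities, sizes: dict) -> PanelSet:
    """Frequency-difference panels size-matched to ``sizes`` (class -> n)."""
    from .panels import MarkerPanel

    panels = {}
    for k, n in sizes.items():
        if n < 1:
            continue
        genes = frequency_rank_reference(probs, k, n)
        panels[k] = MarkerPanel(
            class_name=k, genes=genes, weights=[0.0] * len(genes),
            config={"method": "frequency_rank_reference"},
            achieved_rate=1.0, objective=0.0, solver_status="greedy",
        )
    return PanelSet(panels=panels)
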