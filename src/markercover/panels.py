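"""Marker panels: the per-class output of the covering solver."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import DataError

SOLVER_STATUSES = ("optimal", "gap_reported", "greedy", "infeasible")


@dataclass
class MarkerPanel:
    """Genes selected for one class, with the weights and config that produced them.

    ``achieved_rate`` is the covering rate recomputed from the returned genes
    on the training cells, never taken from the solver's own bookkeeping.
    """

    class_name: str
    genes: List[str]
    weights: List[float]
    config: dict
    achieved_rate: float
    objective: float
    solver_status: str
    mip_gap: Optional[float] = None

    def __post_init__(self):
        if self.solver_status not in SOLVER_STATUSES:
            raise DataError(
                f"solver_status must be one of {SOLVER_STATUSES}, "
                f"got {self.solver_status!r}"
            )
        if len(self.genes) != len(set(self.genes)):
            raise DataError(f"panel for {self.class_name!r} has duplicate genes")
        if len(self.genes) != len(self.weights):
            raise DataError("genes and weights must have equal length")
        self.weights = [float(w) for w in self.weights]
        self.objective = float(self.objective)
        self.achieved_rate = float(self.achieved_rate)
        if self.genes and not np.isclose(
            self.objective, float(np.sum(self.weights)), rtol=1e-9, atol=1e-9
        ):
            raise DataError(
                f"objective {self.objective} != sum of weights "
                f"{float(np.sum(self.weights))}"
            )

    @property
    def size(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "class_name": self.class_name,
            "genes": list(self.genes),
            "weights": list(self.weights),
            "config": dict(self.config),
            "achieved_rate": self.achieved_rate,
            "objective": self.objective,
            "solver_status": self.solver_status,
            "mip_gap": self.mip_gap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(
            class_name=d["class_name"],
            genes=list(d["genes"]),
            weights=list(d["weights"]),
            config=dict(d.get("config", {})),
            achieved_rate=d["achieved_rate"],
            objective=d["objective"],
            solver_status=d["solver_status"],
            mip_gap=d.get("mip_gap"),
        )


@dataclass
class PanelSet:
    """One panel per class plus the global (union) panel."""

    panels: Dict[str, MarkerPanel] = field(default_factory=dict)

    def __post_init__(self):
        for name, p in self.panels.items():
            if p.class_name != name:
                raise DataError(
                    f"panel keyed {name!r} has class_name {p.class_name!r}"
                )

    @property
    def class_names(self) -> List[str]:
        return list(self.panels.keys())

    @property
    def global_panel(self) -> List[str]:
        """Union of all per-class genes, in first-appearance order (no duplicates)."""
        seen = []
        seen_set = set()
        for p in self.panels.values():
            for g in p.genes:
                if g not in seen_set:
                    seen.append(g)
                    seen_set.add(g)
        return seen

    def __getitem__(self, class_name: str) -> MarkerPanel:
        return self.panels[class_name]

    def __iter__(self):
        return iter(self.panels.values())

    def __len__(self) -> int:
        return len(self.panels)
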