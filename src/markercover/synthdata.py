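"""Zero-inflated labeled count matrices with planted class-specific markers.

Each gene-class pair has a Bernoulli detection probability; detected entries
get a positive count of 1 + Poisson(lambda), so binarizing at theta = 0
recovers the Bernoulli layer exactly. An optional sibling mechanism makes a
pair of classes share a fraction rho of their marker sets, planting the
redundancy trap that distinguishes covering panels from one-gene-at-a-time
rankings.

Randomness is driven by one seed; each gene draws from its own
deterministically derived substream, so adding genes never perturbs the
counts of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .errors import DataError
from .matrix import ExpressionMatrix, binarize


@dataclass
class SimConfig:
    n_classes: int = 3
    cells_per_class: int = 200
    n_markers_per_class: int = 10
    n_background_genes: int = 200
    p_in: float = 0.9
    p_out: float = 0.05
    p_bg: float = 0.25            # scalar or sequence of length n_classes
    dropout: float = 0.0
    lambda_marker: float = 3.0    # positive counts are 1 + Poisson(lambda)
    lambda_background: float = 1.0
    sibling_pairs: Sequence[Tuple[int, int]] = field(default_factory=tuple)
    sibling_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise DataError(f"n_classes must be >= 2, got {self.n_classes}")
        for name in ("p_in", "p_out", "dropout", "sibling_rho"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0, 1], got {v}")
        p_bg = np.atleast_1d(np.asarray(self.p_bg, dtype=float))
        if p_bg.min() < 0 or p_bg.max() > 1:
            raise DataError("p_bg values must lie in [0, 1]")
        if p_bg.size not in (1, self.n_classes):
            raise DataError(
                f"p_bg must be scalar or length {self.n_classes}, got {p_bg.size}"
            )
        if self.p_in <= self.p_out:
            raise DataError(
                f"planted markers need p_in > p_out, got {self.p_in} <= {self.p_out}"
            )
        if self.cells_per_class < 1 or self.n_markers_per_class < 1:
            raise DataError("cells_per_class and n_markers_per_class must be >= 1")
        if self.n_background_genes < 0:
            raise DataError("n_background_genes must be >= 0")
        for (a, b) in self.sibling_pairs:
            if not (0 <= a < self.n_classes and 0 <= b < self.n_classes) or a == b:
                raise DataError(f"invalid sibling pair ({a}, {b})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sibling_pairs"] = [list(p) for p in self.sibling_pairs]
        if not np.isscalar(d["p_bg"]):
            d["p_bg"] = list(np.atleast_1d(d["p_bg"]).astype(float))
        return d


@dataclass
class SimTruth:
    """Ground truth of a simulation: planted markers and realized frequencies."""

    markers: Dict[str, List[str]]                 # class -> planted marker IDs
    shared: Dict[Tuple[str, str], List[str]]      # sibling pair -> shared IDs
    detect_prob: np.ndarray                       # genes x classes design probs
    realized_freq: np.ndarray                     # genes x classes empirical
    gene_ids: List[str]
    classes: List[str]

    def all_marker_genes(self) -> set:
        out = set()
        for genes in self.markers.values():
            out.update(genes)
        return out


def _class_name(k: int) -> str:
    return f"class_{k}"


def simulate(cfg: SimConfig):
    """Draw one labeled count matrix; returns (ExpressionMatrix, SimTruth)."""
    K = cfg.n_classes
    n_mark = cfg.n_markers_per_class
    classes = [_class_name(k) for k in range(K)]
    n_cells = K * cfg.cells_per_class
    labels = np.repeat(classes, cfg.cells_per_class)
    cell_ids = np.array(
        [f"cell_{i:05d}" for i in range(n_cells)], dtype=object
    )

    # gene layout: per-class markers first, then shared sibling markers,
    # then background
    gene_ids: List[str] = []
    markers: Dict[str, List[str]] = {c: [] for c in classes}
    shared: Dict[Tuple[str, str], List[str]] = {}
    rows_prob: List[np.ndarray] = []
    lambdas: List[float] = []

    n_shared = int(round(cfg.sibling_rho * n_mark)) if cfg.sibling_pairs else 0
    sibling_members = set()
    for (a, b) in cfg.sibling_pairs:
        sibling_members.update((a, b))

    for k in range(K):
        n_private = n_mark - n_shared if k in sibling_members else n_mark
        for j in range(n_private):
            gid = f"MK{k}_{j:03d}"
            gene_ids.append(gid)
            markers[classes[k]].append(gid)
            p = np.full(K, cfg.p_out)
            p[k] = cfg.p_in
            rows_prob.append(p)
            lambdas.append(cfg.lambda_marker)

    for (a, b) in cfg.sibling_pairs:
        pair_key = (classes[a], classes[b])
        shared[pair_key] = []
        for j in range(n_shared):
            gid = f"SH{a}x{b}_{j:03d}"
            gene_ids.append(gid)
            shared[pair_key].append(gid)
            markers[classes[a]].append(gid)
            markers[classes[b]].append(gid)
            p = np.full(K, cfg.p_out)
            p[a] = cfg.p_in
            p[b] = cfg.p_in
            rows_prob.append(p)
            lambdas.append(cfg.lambda_marker)

    p_bg = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.p_bg, dtype=float)), (K,)
    ).copy()
    for j in range(cfg.n_background_genes):
        gene_ids.append(f"BG_{j:04d}")
        rows_prob.append(p_bg.copy())
        lambdas.append(cfg.lambda_background)

    detect_prob = np.vstack(rows_prob) if rows_prob else np.zeros((0, K))
    class_of_cell = np.repeat(np.arange(K), cfg.cells_per_class)

    rows, cols, data = [], [], []
    for g, gid in enumerate(gene_ids):
        rng = np.random.default_rng([cfg.seed, g])
        p_per_cell = detect_prob[g, class_of_cell] * (1.0 - cfg.dropout)
        expressed = rng.random(n_cells) < p_per_cell
        idx = np.flatnonzero(expressed)
        if idx.size:
            counts = 1 + rng.poisson(lambdas[g], size=idx.size)
            rows.extend([g] * idx.size)
            cols.extend(idx.tolist())
            data.extend(counts.tolist())

    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(gene_ids), n_cells), dtype=float
    )
    em = ExpressionMatrix(
        counts=counts,
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=cell_ids,
        labels=labels,
    )
    b = binarize(em, 0.0)
    realized = np.zeros((len(gene_ids), K))
    for k in range(K):
        cols_k = np.flatnonzero(class_of_cell == k)
        realized[:, k] = (
            np.asarray(b.indicator[:, cols_k].sum(axis=1)).ravel() / cols_k.size
        )
    truth = SimTruth(
        markers=markers, shared=shared, detect_prob=detect_prob,
        realized_freq=realized, gene_ids=list(gene_ids), classes=classes,
    )
    return em, truth


def sibling_scenario(cfg: SimConfig, rho: Optional[float] = None):
    """Simulation where classes 0 and 1 share a fraction rho of their markers."""
    if rho is None:
        rho = cfg.sibling_rho
    if not (0.0 <= rho <= 1.0):
        raise DataError(f"rho must be in [0, 1], got {rho}")
    cfg = replace(cfg, sibling_pairs=((0, 1),), sibling_rho=rho)
    return simulate(cfg)
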