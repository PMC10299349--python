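"""Depth-d, rate-(1-alpha) minimal-weight partial set-multi-cover per class.

For a target class with cells S and candidate genes G, select binary z_g
minimizing sum_g w_g z_g subject to

    sum_g z_g u_g(c) >= d * s(c)   for every cell c in S
    sum_c s(c)       >= ceil((1 - alpha) * |S|)

with z, s binary: at least a fraction 1 - alpha of the class's cells must
express at least d selected genes. Three interchangeable back-ends solve the
same instance: an exact MILP (HiGHS via scipy), an exhaustive enumeration
used as a test oracle on small instances, and a greedy heuristic whose
objective upper-bounds the optimum.

Low-level solvers work on a dense 0/1 array ``U`` of shape
(n_cells, n_genes) — cells of the target class by candidate genes — plus a
weight vector. ``fit_all_classes`` wires them to labeled expression data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import DataError, InfeasibleError, SolverError
from .matrix import ExpressionMatrix, binarize
from .panels import MarkerPanel, PanelSet
from .weights import (
    DEFAULT_MAX_WEIGHT,
    DEFAULT_MIN_EXPR,
    SCHEMES,
    candidate_set,
    compute_weights,
    estimate_mean_lognorm,
    estimate_probabilities,
)

SOLVERS = ("ilp", "greedy", "brute_force")


@dataclass
class CoverConfig:
    """All knobs of a covering run; stored verbatim in every panel produced."""

    depth: int = 1
    alpha: float = 0.0
    theta: float = 0.0
    scheme: str = "mean_ratio"
    min_expr: float = DEFAULT_MIN_EXPR
    max_weight: float = DEFAULT_MAX_WEIGHT
    solver: str = "ilp"
    time_limit: float = 600.0
    mip_gap: float = 0.0
    seed: int = 0
    target_sum: float = 1e4   # lognorm_ratio normalization target

    def __post_init__(self):
        if int(self.depth) != self.depth or self.depth < 1:
            raise DataError(f"depth must be a positive integer, got {self.depth}")
        self.depth = int(self.depth)
        if not (0.0 <= self.alpha < 1.0):
            raise DataError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.theta < 0:
            raise DataError(f"theta must be >= 0, got {self.theta}")
        if self.scheme not in SCHEMES:
            raise DataError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.solver not in SOLVERS:
            raise DataError(f"unknown solver {self.solver!r}; choose from {SOLVERS}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CoverSolution:
    """Solver output on one instance, with coverage recomputed from the panel."""

    selected: np.ndarray          # bool per candidate gene
    covered: np.ndarray           # bool per class cell, from the returned panel
    objective: float
    n_required: int
    status: str                   # optimal | gap_reported | greedy | infeasible
    mip_gap: Optional[float] = None
    diagnostic: Optional[dict] = None

    @property
    def achieved_rate(self) -> float:
        if self.covered.size == 0:
            return 0.0
        return float(np.mean(self.covered))

    @property
    def feasible(self) -> bool:
        return self.status != "infeasible"


def n_required(n_cells: int, alpha: float) -> int:
    """ceil((1 - alpha) * n_cells), guarded against float noise like 0.9*10."""
    return int(math.ceil((1.0 - alpha) * n_cells - 1e-9))


def _check_instance(U, w):
    U = np.asarray(U)
    if U.ndim != 2:
        raise DataError("U must be 2-dimensional (cells x genes)")
    U = (U > 0).astype(np.int8)
    w = np.asarray(w, dtype=float)
    if w.shape != (U.shape[1],):
        raise DataError(f"{w.shape[0] if w.ndim else 0} weights for {U.shape[1]} genes")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise DataError("solver weights must be finite and non-negative")
    return U, w


def feasibility_check(U, depth: int, alpha: float) -> dict:
    """Can the full candidate set cover enough cells at this depth?

    Returns a diagnostic dict with ``feasible``, ``max_coverable`` (cells
    expressing >= depth candidates), ``n_required`` and
    ``max_feasible_rate``.
    """
    U = (np.asarray(U) > 0).astype(np.int8)
    n_cells = U.shape[0]
    depth_per_cell = U.sum(axis=1)
    max_coverable = int(np.sum(depth_per_cell >= depth))
    n_req = n_required(n_cells, alpha)
    return {
        "feasible": max_coverable >= n_req,
        "max_coverable": max_coverable,
        "n_required": n_req,
        "n_cells": n_cells,
        "max_feasible_rate": max_coverable / n_cells if n_cells else 0.0,
    }


def _coverage(U, selected, depth):
    return (U @ selected.astype(np.int64)) >= depth


def _infeasible_solution(U, depth, alpha, diag=None) -> CoverSolution:
    if diag is None:
        diag = feasibility_check(U, depth, alpha)
    return CoverSolution(
        selected=np.zeros(U.shape[1], dtype=bool),
        covered=np.zeros(U.shape[0], dtype=bool),
        objective=float("inf"),
        n_required=diag["n_required"],
        status="infeasible",
        diagnostic=diag,
    )


def solve_cover(U, w, config: CoverConfig, z0=None) -> CoverSolution:
    """Solve one covering instance with the back-end named in ``config.solver``.

    ``z0`` (bool per gene) forces those genes into the solution — the nested
    expansion constraint z_g >= z0_g.
    """
    if config.solver == "ilp":
        return _solve_milp(U, w, config, z0=z0)
    if config.solver == "greedy":
        return greedy_cover(U, w, config, z0=z0)
    return brute_force_cover(U, w, config, z0=z0)


def _solve_milp(U, w, config: CoverConfig, z0=None) -> CoverSolution:
    U, w = _check_instance(U, w)
    n_cells, n_genes = U.shape
    depth, alpha = config.depth, config.alpha
    n_req = n_required(n_cells, alpha)

    if z0 is not None:
        z0 = np.asarray(z0, dtype=bool)
        if z0.shape != (n_genes,):
            raise DataError("z0 length does not match number of candidate genes")
    if n_req == 0:
        sel = z0.copy() if z0 is not None else np.zeros(n_genes, dtype=bool)
        return CoverSolution(
            selected=sel, covered=_coverage(U, sel, depth),
            objective=float(w @ sel), n_required=0, status="optimal", mip_gap=0.0,
        )
    if n_genes == 0:
        return _infeasible_solution(U, depth, alpha)

    diag = feasibility_check(U, depth, alpha)
    if not diag["feasible"]:
        return _infeasible_solution(U, depth, alpha, diag)

    # variables: [z_1..z_G, s_1..s_C]
    c = np.concatenate([w, np.zeros(n_cells)])
    A_cells = sp.hstack(
        [sp.csr_matrix(U), sp.diags([-float(depth)] * n_cells)], format="csr"
    )
    A_quota = sp.hstack(
        [sp.csr_matrix((1, n_genes)), sp.csr_matrix(np.ones((1, n_cells)))],
        format="csr",
    )
    constraints = [
        LinearConstraint(A_cells, lb=0, ub=np.inf),
        LinearConstraint(A_quota, lb=n_req, ub=np.inf),
    ]
    lb = np.zeros(n_genes + n_cells)
    if z0 is not None:
        lb[:n_genes][z0] = 1.0
    bounds = Bounds(lb=lb, ub=np.ones(n_genes + n_cells))
    options = {"mip_rel_gap": float(config.mip_gap)}
    if config.time_limit and np.isfinite(config.time_limit):
        options["time_limit"] = float(config.time_limit)

    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n_genes + n_cells),
        bounds=bounds,
        options=options,
    )

    if res.status == 2:  # proven infeasible (should not happen after the check)
        return _infeasible_solution(U, depth, alpha, diag)
    if res.x is None:
        raise SolverError(f"MILP back-end failed: {res.message}")

    selected = res.x[:n_genes] > 0.5
    covered = _coverage(U, selected, depth)
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    if res.status == 0 and gap <= max(config.mip_gap, 1e-9):
        status = "optimal"
    else:
        status = "gap_reported"
    return CoverSolution(
        selected=selected, covered=covered, objective=float(w @ selected),
        n_required=n_req, status=status, mip_gap=gap,
    )


def brute_force_cover(U, w, config: CoverConfig, z0=None, cap: int = 20) -> CoverSolution:
    """Exhaustive oracle: enumerate gene subsets, return a global optimum.

    Subsets are visited by increasing cardinality; ties on objective break
    toward fewer genes, then lexicographically smaller index tuples, so the
    result is deterministic. Only for small instances (<= ``cap`` free genes).
    """
    U, w = _check_instance(U, w)
    n_cells, n_genes = U.shape
    depth, alpha = config.depth, config.alpha
    n_req = n_required(n_cells, alpha)

    forced = np.zeros(n_genes, dtype=bool)
    if z0 is not None:
        forced = np.asarray(z0, dtype=bool)
        if forced.shape != (n_genes,):
            raise DataError("z0 length does not match number of candidate genes")
    free = np.flatnonzero(~forced)
    if free.size > cap:
        raise DataError(
            f"brute force capped at {cap} free genes, got {free.size}"
        )

    base_depth = U[:, forced].sum(axis=1)
    base_obj = float(w[forced].sum())
    cols = [U[:, g] for g in free]

    best = None  # (objective, cardinality, idx_tuple, selected)
    for r in range(0, free.size + 1):
        for combo in itertools.combinations(range(free.size), r):
            depth_per_cell = base_depth.copy()
            for i in combo:
                depth_per_cell = depth_per_cell + cols[i]
            if int(np.sum(depth_per_cell >= depth)) < n_req:
                continue
            obj = base_obj + float(sum(w[free[i]] for i in combo))
            key = (obj, forced.sum() + r, combo)
            if best is None or key < best[0]:
                sel = forced.copy()
                sel[free[list(combo)]] = True
                best = (key, sel)
    if best is None:
        return _infeasible_solution(U, depth, alpha)
    sel = best[1]
    return CoverSolution(
        selected=sel, covered=_coverage(U, sel, depth),
        objective=float(w @ sel), n_required=n_req, status="optimal", mip_gap=0.0,
    )


def greedy_cover(U, w, config: CoverConfig, z0=None) -> CoverSolution:
    """Heuristic fallback for instances too large for exact solving.

    Repeatedly adds the gene with the best (reduction in residual coverage
    demand over the n_required easiest-to-cover cells) per unit weight. The
    returned objective upper-bounds the exact optimum by construction.
    """
    U, w = _check_instance(U, w)
    n_cells, n_genes = U.shape
    depth, alpha = config.depth, config.alpha
    n_req = n_required(n_cells, alpha)
    eps = 1e-12

    selected = np.zeros(n_genes, dtype=bool)
    if z0 is not None:
        z0 = np.asarray(z0, dtype=bool)
        if z0.shape != (n_genes,):
            raise DataError("z0 length does not match number of candidate genes")
        selected = z0.copy()

    def residual(depth_per_cell):
        deficits = np.clip(depth - depth_per_cell, 0, None)
        deficits = np.sort(deficits)
        return int(deficits[:n_req].sum())

    depth_per_cell = U[:, selected].sum(axis=1)
    demand = residual(depth_per_cell)
    while demand > 0:
        best = None  # (score, -gain, weight, index)
        for g in range(n_genes):
            if selected[g]:
                continue
            gain = demand - residual(depth_per_cell + U[:, g])
            if gain <= 0:
                continue
            score = gain / max(w[g], eps)
            key = (-score, w[g], g)
            if best is None or key < best[0]:
                best = (key, g, gain)
        if best is None:
            return _infeasible_solution(U, depth, alpha)
        g = best[1]
        selected[g] = True
        depth_per_cell = depth_per_cell + U[:, g]
        demand -= best[2]

    covered = _coverage(U, selected, depth)
    return CoverSolution(
        selected=selected, covered=covered, objective=float(w @ selected),
        n_required=n_req, status="greedy",
    )


def nested_expand(U, w, config: CoverConfig, z0) -> CoverSolution:
    """Re-solve at a (larger) depth with the previous panel forced in.

    ``z0`` is a bool mask over the same candidate gene axis as ``U``. The
    result is a superset of z0 satisfying the depth-``config.depth`` covering
    constraint at rate 1 - alpha.
    """
    z0 = np.asarray(z0, dtype=bool)
    return solve_cover(U, w, config, z0=z0)


# ---------------------------------------------------------------------------
# high-level driver


def _candidate_order(gene_ids, weights_col, mask):
    """Candidate gene indices in a fixed deterministic order: weight, then ID."""
    idx = np.flatnonzero(mask)
    order = sorted(idx, key=lambda i: (weights_col[i], str(gene_ids[i])))
    return np.asarray(order, dtype=int)


def build_class_instance(b, weights_table, probs, class_name, config: CoverConfig):
    """Restrict the binary matrix to one class's cells and candidate genes.

    Returns (U, w, candidate_gene_ids) with genes presented in a fixed
    deterministic order (ascending weight, then gene ID).
    """
    mask = candidate_set(
        weights_table, probs, class_name,
        min_expr=config.min_expr, max_weight=config.max_weight,
    )
    wcol = weights_table.column(class_name)
    order = _candidate_order(b.gene_ids, wcol, mask)
    cells = b.class_indices(class_name)
    U = np.asarray(b.indicator[order][:, cells].todense()).T  # cells x genes
    return U, wcol[order], b.gene_ids[order]


def solution_to_panel(
    sol: CoverSolution, class_name, gene_ids, w, config: CoverConfig
) -> MarkerPanel:
    sel = np.flatnonzero(sol.selected)
    order = sorted(sel, key=lambda i: (w[i], str(gene_ids[i])))
    genes = [str(gene_ids[i]) for i in order]
    weights = [float(w[i]) for i in order]
    return MarkerPanel(
        class_name=str(class_name),
        genes=genes,
        weights=weights,
        config=config.to_dict(),
        achieved_rate=sol.achieved_rate,
        objective=float(sum(weights)) if genes else 0.0,
        solver_status=sol.status,
        mip_gap=sol.mip_gap,
    )


def fit_class(b, probs, weights_table, class_name, config: CoverConfig) -> MarkerPanel:
    """Run filtering + covering for a single class and package the result."""
    U, w, gene_ids = build_class_instance(b, weights_table, probs, class_name, config)
    if U.shape[1] == 0:
        sol = _infeasible_solution(U, config.depth, config.alpha)
    else:
        sol = solve_cover(U, w, config)
    return solution_to_panel(sol, class_name, gene_ids, w, config)


def fit_all_classes(m: ExpressionMatrix, config: CoverConfig, labels=None):
    """Fit one covering panel per class.

    Returns ``(PanelSet, report)`` where ``report`` is a list of per-class
    dicts (candidate-set size, objective, achieved rate, status, error).
    Per-class failures are recorded without aborting the other classes.
    """
    if labels is None:
        labels = m.labels
    if labels is None:
        raise DataError("class labels are required to fit panels")
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DataError(f"need at least 2 classes, got {len(classes)}")

    b = binarize(m, config.theta)
    b.labels = labels
    probs = estimate_probabilities(b, labels)
    means = None
    if config.scheme == "lognorm_ratio":
        means = estimate_mean_lognorm(m, labels, target_sum=config.target_sum)
    wt = compute_weights(probs, config.scheme, means=means)

    panels = {}
    report = []
    for k in classes:
        entry = {"class": k, "n_cells": int(np.sum(labels == k))}
        try:
            U, w, gene_ids = build_class_instance(b, wt, probs, k, config)
            entry["n_candidates"] = int(U.shape[1])
            if U.shape[1] == 0:
                sol = _infeasible_solution(U, config.depth, config.alpha)
            else:
                sol = solve_cover(U, w, config)
            panel = solution_to_panel(sol, k, gene_ids, w, config)
            panels[k] = panel
            entry.update(
                status=panel.solver_status,
                panel_size=panel.size,
                objective=panel.objective if panel.genes else None,
                achieved_rate=panel.achieved_rate,
                diagnostic=sol.diagnostic,
            )
        except Exception as exc:  # noqa: BLE001 - per-class isolation by contract
            entry["status"] = "error"
            entry["error"] = str(exc)
        report.append(entry)
    return PanelSet(panels=panels), report


def expand_panel(
    m: ExpressionMatrix,
    panel: MarkerPanel,
    new_depth: int,
    new_alpha: Optional[float] = None,
    labels=None,
) -> MarkerPanel:
    """Nested expansion of a fitted panel to a larger depth on its own data.

    The original config travels with the panel; only depth (and optionally
    alpha) change. Every original gene must still pass the candidate filter,
    otherwise the configs are inconsistent and an error is raised.
    """
    old = CoverConfig(**panel.config)
    if new_depth < old.depth:
        raise DataError(
            f"expansion depth {new_depth} < original depth {old.depth}"
        )
    cfg_kwargs = old.to_dict()
    cfg_kwargs["depth"] = int(new_depth)
    if new_alpha is not None:
        cfg_kwargs["alpha"] = float(new_alpha)
    config = CoverConfig(**cfg_kwargs)

    if labels is None:
        labels = m.labels
    if labels is None:
        raise DataError("class labels are required to expand a panel")
    labels = np.asarray(labels, dtype=object)
    b = binarize(m, config.theta)
    b.labels = labels
    probs = estimate_probabilities(b, labels)
    means = None
    if config.scheme == "lognorm_ratio":
        means = estimate_mean_lognorm(m, labels, target_sum=config.target_sum)
    wt = compute_weights(probs, config.scheme, means=means)

    U, w, gene_ids = build_class_instance(b, wt, probs, panel.class_name, config)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in panel.genes if g not in gene_pos]
    if missing:
        raise DataError(
            f"panel genes not in the candidate set for class "
            f"{panel.class_name!r}: {missing} (config mismatch)"
        )
    z0 = np.zeros(len(gene_ids), dtype=bool)
    z0[[gene_pos[g] for g in panel.genes]] = True
    sol = nested_expand(U, w, config, z0)
    return solution_to_panel(sol, panel.class_name, gene_ids, w, config)


def expand_panelset(
    m: ExpressionMatrix,
    ps: PanelSet,
    new_depth: int,
    new_alpha: Optional[float] = None,
    labels=None,
):
    """Expand every feasible panel in a set; returns (PanelSet, report)."""
    panels = {}
    report = []
    for panel in ps:
        entry = {"class": panel.class_name}
        try:
            if panel.solver_status == "infeasible":
                panels[panel.class_name] = panel
                entry["status"] = "skipped_infeasible"
            else:
                new = expand_panel(m, panel, new_depth, new_alpha, labels=labels)
                panels[panel.class_name] = new
                entry.update(status=new.solver_status, panel_size=new.size,
                             objective=new.objective)
        except Exception as exc:  # noqa: BLE001
            entry["status"] = "error"
            entry["error"] = str(exc)
        report.append(entry)
    return PanelSet(panels=panels), report
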