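import numpy as np
import pytest

from markercover.cover import (
    CoverConfig,
    brute_force_cover,
    expand_panel,
    feasibility_check,
    fit_all_classes,
    greedy_cover,
    n_required,
    nested_expand,
    solve_cover,
)
from markercover.errors import DataError
from markercover.matrix import binarize
from markercover.synthdata import SimConfig, simulate
from markercover.transfer import class_covering_rates

from conftest import make_matrix, random_instance


class TestConfig:
    def test_validation(self):
        with pytest.raises(DataError):
            CoverConfig(depth=0)
        with pytest.raises(DataError):
            CoverConfig(alpha=1.0)
        with pytest.raises(DataError):
            CoverConfig(alpha=-0.1)
        with pytest.raises(DataError):
            CoverConfig(theta=-1)
        with pytest.raises(DataError):
            CoverConfig(scheme="nope")
        with pytest.raises(DataError):
            CoverConfig(solver="cplex")

    def test_n_required_float_guard(self):
        # 0.9 * 10 = 9.000000000000002 in floats; must not round up to 10
        assert n_required(10, 0.1) == 9
        assert n_required(4, 0.25) == 3
        assert n_required(4, 0.5) == 2
        assert n_required(7, 0.0) == 7


class TestFeasibility:
    def test_full_coverage_feasible(self, abc_instance):
        U, _ = abc_instance
        diag = feasibility_check(U, 1, 0.0)
        assert diag["feasible"] and diag["max_coverable"] == 4

    def test_uncoverable_cell(self):
        U = np.array([[1], [0]])
        diag = feasibility_check(U, 1, 0.0)
        assert not diag["feasible"]
        assert diag["max_feasible_rate"] == 0.5

    def test_abc_depth_two(self, abc_instance):
        U, _ = abc_instance
        diag = feasibility_check(U, 2, 0.0)
        assert diag["feasible"] and diag["max_coverable"] == 4


class TestSolveCover:
    # expected objectives frozen from exhaustive enumeration of all gene
    # subsets of the ABC fixture
    @pytest.mark.parametrize("depth,alpha,expected", [
        (1, 0.0, 0.6),
        (2, 0.0, 1.1),
        (2, 0.5, 0.6),
    ])
    def test_abc_objectives(self, abc_instance, depth, alpha, expected):
        U, w = abc_instance
        sol = solve_cover(U, w, CoverConfig(depth=depth, alpha=alpha))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(expected)
        assert sol.achieved_rate >= 1 - alpha

    def test_abc_d2_selects_all_three(self, abc_instance):
        U, w = abc_instance
        sol = solve_cover(U, w, CoverConfig(depth=2, alpha=0.0))
        assert sol.selected.all()

    def test_singleton_optimum(self):
        # one cheap gene expressed everywhere beats any combination
        U = np.array([[1, 1], [1, 0], [1, 1]])
        w = np.array([0.1, 0.05])
        sol = solve_cover(U, w, CoverConfig(depth=1, alpha=0.0))
        assert sol.objective == pytest.approx(0.1)
        assert list(sol.selected) == [True, False]

    def test_empty_candidate_set_infeasible(self):
        sol = solve_cover(np.zeros((3, 0)), np.zeros(0), CoverConfig())
        assert sol.status == "infeasible"

    def test_infeasible_reports_diagnostic(self):
        U = np.array([[1], [0]])
        sol = solve_cover(U, np.array([0.5]), CoverConfig(depth=1, alpha=0.0))
        assert sol.status == "infeasible"
        assert sol.diagnostic["max_feasible_rate"] == 0.5

    def test_uncoverable_cells_consume_alpha_budget(self):
        # 4 cells, one expresses nothing; alpha=0.25 tolerates exactly it
        U = np.array([[1], [1], [1], [0]])
        w = np.array([0.2])
        sol = solve_cover(U, w, CoverConfig(depth=1, alpha=0.25))
        assert sol.feasible and sol.objective == pytest.approx(0.2)

    def test_nonfinite_weights_rejected(self, abc_instance):
        U, w = abc_instance
        w = w.copy()
        w[0] = np.inf
        with pytest.raises(DataError, match="finite"):
            solve_cover(U, w, CoverConfig())


class TestBruteForce:
    def test_matches_spec_objective(self, abc_instance):
        U, w = abc_instance
        sol = brute_force_cover(U, w, CoverConfig(depth=1, alpha=0.0))
        assert sol.objective == pytest.approx(0.6)

    def test_infeasible_agrees_with_ilp(self):
        U = np.array([[1], [0]])
        cfg = CoverConfig(depth=1, alpha=0.0)
        w = np.array([0.5])
        assert brute_force_cover(U, w, cfg).status == "infeasible"
        assert solve_cover(U, w, cfg).status == "infeasible"

    def test_empty_candidates_infeasible(self):
        sol = brute_force_cover(np.zeros((2, 0)), np.zeros(0), CoverConfig())
        assert sol.status == "infeasible"

    def test_cap_enforced(self):
        U = np.ones((2, 25))
        with pytest.raises(DataError, match="capped"):
            brute_force_cover(U, np.ones(25), CoverConfig(), cap=20)


class TestGreedy:
    def test_dominant_gene(self):
        U = np.array([[1, 1], [1, 0], [1, 1]])
        w = np.array([0.1, 0.09])
        sol = greedy_cover(U, w, CoverConfig(depth=1, alpha=0.0))
        assert sol.status == "greedy"
        assert sol.objective == pytest.approx(0.1)

    def test_bounded_below_by_optimum(self, abc_instance):
        U, w = abc_instance
        cfg = CoverConfig(depth=1, alpha=0.0)
        g = greedy_cover(U, w, cfg)
        assert g.feasible
        assert g.objective >= 0.6 - 1e-12
        assert g.achieved_rate >= 1.0

    def test_infeasible(self):
        U = np.array([[1], [0]])
        sol = greedy_cover(U, np.array([0.5]), CoverConfig(depth=1, alpha=0.0))
        assert sol.status == "infeasible"

    def test_dominance_on_random_instances(self, rng):
        for _ in range(30):
            U, w, cfg = random_instance(rng)
            opt = brute_force_cover(U, w, cfg)
            g = greedy_cover(U, w, cfg)
            assert (opt.status == "infeasible") == (g.status == "infeasible")
            if opt.feasible:
                assert g.objective >= opt.objective - 1e-9
                assert g.achieved_rate >= 1 - cfg.alpha


class TestNestedExpand:
    def test_abc_expansion(self, abc_instance):
        # frozen from brute force with the superset constraint: d=1/alpha=.25
        # selects {A} (objective 0.3); expanding to d=2/alpha=.5 gives {A,B}
        U, w = abc_instance
        sol1 = solve_cover(U, w, CoverConfig(depth=1, alpha=0.25))
        assert list(sol1.selected) == [True, False, False]
        assert sol1.objective == pytest.approx(0.3)
        sol2 = nested_expand(U, w, CoverConfig(depth=2, alpha=0.5), sol1.selected)
        assert list(sol2.selected) == [True, True, False]
        assert sol2.objective == pytest.approx(0.6)

    def test_same_depth_is_identity(self, abc_instance):
        U, w = abc_instance
        cfg = CoverConfig(depth=1, alpha=0.0)
        sol = solve_cover(U, w, cfg)
        sol2 = nested_expand(U, w, cfg, sol.selected)
        assert list(sol2.selected) == list(sol.selected)
        assert sol2.objective == pytest.approx(sol.objective)

    def test_empty_initial_panel_equals_solve(self, abc_instance):
        U, w = abc_instance
        cfg = CoverConfig(depth=2, alpha=0.0)
        plain = solve_cover(U, w, cfg)
        nested = nested_expand(U, w, cfg, np.zeros(3, dtype=bool))
        assert nested.objective == pytest.approx(plain.objective)

    def test_superset_and_dominance_on_random_instances(self, rng):
        checked = 0
        while checked < 25:
            U, w, cfg = random_instance(rng, max_genes=8, max_cells=20)
            if cfg.depth >= 3:
                continue
            base = solve_cover(U, w, cfg)
            if not base.feasible:
                continue
            cfg2 = CoverConfig(depth=cfg.depth + 1, alpha=cfg.alpha)
            grown = nested_expand(U, w, cfg2, base.selected)
            plain = solve_cover(U, w, cfg2)
            assert (grown.status == "infeasible") == (plain.status == "infeasible")
            if grown.feasible:
                assert np.all(grown.selected[base.selected])
                assert grown.objective >= plain.objective - 1e-9
            checked += 1


class TestMonotonicity:
    def test_objective_monotone_in_depth_and_alpha(self, rng):
        for _ in range(20):
            U, w, _ = random_instance(rng, max_genes=8, max_cells=20)
            objs = {}
            for d in (1, 2, 3):
                for a in (0.0, 0.1, 0.25):
                    sol = solve_cover(U, w, CoverConfig(depth=d, alpha=a))
                    objs[(d, a)] = sol.objective if sol.feasible else np.inf
            for a in (0.0, 0.1, 0.25):
                assert objs[(1, a)] <= objs[(2, a)] + 1e-9
                assert objs[(2, a)] <= objs[(3, a)] + 1e-9
            for d in (1, 2, 3):
                assert objs[(d, 0.25)] <= objs[(d, 0.1)] + 1e-9
                assert objs[(d, 0.1)] <= objs[(d, 0.0)] + 1e-9


class TestFitAllClasses:
    def test_planted_markers_recovered(self):
        em, truth = simulate(SimConfig(seed=11))
        ps, report = fit_all_classes(em, CoverConfig(depth=3, alpha=0.05))
        assert len(ps) == 3
        for panel in ps:
            assert panel.solver_status == "optimal"
            assert set(panel.genes) <= set(truth.markers[panel.class_name])
            assert panel.achieved_rate >= 0.95

    def test_single_class_errors(self):
        m = make_matrix([[1, 0], [0, 1]], labels=["k", "k"])
        with pytest.raises(DataError, match="2 classes"):
            fit_all_classes(m, CoverConfig())

    def test_identical_classes_reported_not_crashed(self):
        # two classes drawn from one distribution: nothing is discriminative
        rng = np.random.default_rng(5)
        counts = (rng.random((20, 40)) < 0.05).astype(float)
        m = make_matrix(counts, labels=["a"] * 20 + ["b"] * 20)
        ps, report = fit_all_classes(m, CoverConfig(depth=1, alpha=0.0))
        assert {e["class"] for e in report} == {"a", "b"}
        for e in report:
            assert e["status"] in ("infeasible", "optimal", "error")

    def test_solver_backends_agree_on_objective(self):
        # low p_bg keeps candidate sets under the brute-force cap
        em, _ = simulate(SimConfig(seed=3, cells_per_class=40,
                                   n_background_genes=30, p_bg=0.02))
        obj = {}
        for solver in ("ilp", "brute_force"):
            ps, _ = fit_all_classes(
                em, CoverConfig(depth=2, alpha=0.05, solver=solver))
            obj[solver] = {p.class_name: p.objective for p in ps}
        assert obj["ilp"].keys() == obj["brute_force"].keys()
        for k in obj["ilp"]:
            assert obj["ilp"][k] == pytest.approx(obj["brute_force"][k])

    def test_deterministic(self):
        em, _ = simulate(SimConfig(seed=7, cells_per_class=50))
        cfg = CoverConfig(depth=2, alpha=0.05)
        ps1, _ = fit_all_classes(em, cfg)
        ps2, _ = fit_all_classes(em, cfg)
        for k in ps1.class_names:
            assert ps1[k].genes == ps2[k].genes
            assert ps1[k].objective == ps2[k].objective


class TestExpandPanel:
    def test_expand_is_superset_and_covers(self):
        em, _ = simulate(SimConfig(seed=13))
        ps, _ = fit_all_classes(em, CoverConfig(depth=2, alpha=0.05))
        for panel in ps:
            grown = expand_panel(em, panel, new_depth=4)
            assert set(panel.genes) <= set(grown.genes)
            b = binarize(em, 0.0)
            rate = class_covering_rates(grown.genes, b, 4).values[panel.class_name]
            assert rate >= 0.95 - 1e-12

    def test_shrinking_depth_rejected(self):
        em, _ = simulate(SimConfig(seed=13, cells_per_class=30))
        ps, _ = fit_all_classes(em, CoverConfig(depth=3, alpha=0.05))
        panel = next(iter(ps))
        with pytest.raises(DataError, match="depth"):
            expand_panel(em, panel, new_depth=1)
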