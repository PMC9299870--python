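"""Diet LP engine: feasibility diagnostics, best diet, nutrient extremes.

The engine is checked against two independent oracles on small problems:
a dense grid search (for problem families whose optimal vertices provably
lie on the grid) and exhaustive vertex enumeration (for arbitrary bound
structures).
"""

import itertools

import numpy as np
import pytest

import dietpair as dp
from dietpair.core import NUTRIENTS
from dietpair.lp import LinearDietProblem

IRON = NUTRIENTS.index("iron")


def make_problem(energy_coef, iron_coef, lower, upper, e_window,
                 subgroup_bounds=None, subgroups=None, rni_iron=3.0,
                 iron_only=True):
    """Assemble a small LP directly in weekly-serving units."""
    n = len(energy_coef)
    nutrient_coef = np.zeros((len(NUTRIENTS), n))
    nutrient_coef[IRON] = iron_coef
    e_lo, e_hi = e_window
    target = (e_lo + e_hi) / 2.0
    tol = (e_hi - e_lo) / (e_hi + e_lo) if e_hi > e_lo else 0.0
    food_ids = [f"f{i}" for i in range(n)]
    if subgroups is None:
        subgroups = {"sg_all": list(range(n))}
    if subgroup_bounds is None:
        subgroup_bounds = {sg: (0.0, float(np.sum(upper)))
                           for sg in subgroups}
    rni = np.ones(len(NUTRIENTS))
    rni[IRON] = rni_iron
    active = None
    if iron_only:
        active = np.zeros(len(NUTRIENTS), dtype=bool)
        active[IRON] = True
    return LinearDietProblem(
        food_ids=food_ids, portions=np.full(n, 100.0),
        energy_coef=np.asarray(energy_coef, dtype=float),
        nutrient_coef=nutrient_coef,
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        subgroup_members=subgroups, subgroup_bounds=subgroup_bounds,
        group_members={"g_all": list(range(n))},
        group_bounds={"g_all": (0.0, float(np.sum(upper)))},
        group_goals={}, energy_target=target, energy_tolerance=tol,
        mode="free_pattern", rni=rni, active=active,
    )


def two_food_toy(**kw):
    """Portions 100 g; energy/serving A=100, B=50 kcal; iron/serving A=1,
    B=2 mg; A in [0,7], B in [0,14]; daily energy fixed at 100 kcal."""
    return make_problem(
        energy_coef=[100 / 7, 50 / 7], iron_coef=[1 / 7, 2 / 7],
        lower=[0, 0], upper=[7, 14], e_window=(100.0, 100.0),
        subgroups={"sg_a": [0], "sg_b": [1]},
        subgroup_bounds={"sg_a": (0.0, 7.0), "sg_b": (0.0, 14.0)}, **kw)


class TestExtremes:
    def test_two_food_toy_max_and_min(self):
        problem = two_food_toy()
        mx = dp.extreme_nutrient_diet(problem, "iron", "max")
        mn = dp.extreme_nutrient_diet(problem, "iron", "min")
        assert mx.objective == pytest.approx(4.0, abs=1e-6)
        assert mn.objective == pytest.approx(1.0, abs=1e-6)

    def test_fbr_floor_raises_minimum(self):
        problem = two_food_toy()
        mn = dp.extreme_nutrient_diet(problem, "iron", "min",
                                      fbr_floors={"sg_b"})
        assert mn.objective == pytest.approx(4.0, abs=1e-6)

    def test_max_at_least_min(self, default_models):
        free = default_models[1]
        for nutrient in ("iron", "calcium", "vitamin_a"):
            mx = free.extreme(nutrient, "max")
            mn = free.extreme(nutrient, "min")
            assert mx.objective >= mn.objective - 1e-9

    def test_solution_satisfies_constraints(self):
        problem = two_food_toy()
        sol = dp.extreme_nutrient_diet(problem, "iron", "max")
        x = sol.servings.to_numpy()
        assert np.all(x >= problem.lower - 1e-6)
        assert np.all(x <= problem.upper + 1e-6)
        assert sol.energy_kcal_day == pytest.approx(100.0, abs=1e-4)

    def test_solver_determinism(self):
        vals = [dp.extreme_nutrient_diet(two_food_toy(), "iron",
                                         "max").objective
                for _ in range(3)]
        assert max(vals) - min(vals) < 1e-7


class TestFeasibility:
    def test_reachable_energy_window(self):
        problem = make_problem([100 / 7], [1 / 7], [0], [14], (100.0, 100.0))
        problem.energy_tolerance = 0.01
        report = dp.check_feasibility(problem)
        assert report.feasible
        lo, hi = report.energy_range
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(200.0, abs=1e-6)

    def test_unreachable_energy_is_diagnosed(self):
        problem = make_problem([100 / 7], [1 / 7], [0], [14],
                               (1200.0, 1200.0))
        problem.energy_tolerance = 0.01
        report = dp.check_feasibility(problem)
        assert not report.feasible
        assert any("energy unreachable" in d for d in report.diagnostics)

    def test_contradictory_bounds_named(self):
        problem = make_problem([100 / 7], [1 / 7], [5], [3], (100.0, 100.0))
        report = dp.check_feasibility(problem)
        assert not report.feasible
        assert any("min" in d and "max" in d for d in report.diagnostics)

    def test_subgroup_min_exceeding_member_maxima_flagged(self):
        problem = make_problem(
            [100 / 7, 50 / 7], [1 / 7, 2 / 7], [0, 0], [2, 2],
            (100.0, 100.0),
            subgroups={"sg": [0, 1]}, subgroup_bounds={"sg": (10.0, 20.0)})
        report = dp.check_feasibility(problem)
        assert not report.feasible
        assert any("exceeds sum of member food maxima" in d
                   for d in report.diagnostics)


class TestBestDiet:
    def test_reachable_rni_caps_t_at_one(self):
        problem = two_food_toy(rni_iron=3.0)
        sol = dp.best_diet(problem)
        assert sol.optimal
        assert sol.objective == pytest.approx(1.0, abs=1e-6)
        assert sol.nutrient_totals["iron"] >= 3.0 - 1e-6

    def test_unreachable_rni_gives_fractional_t(self):
        problem = two_food_toy(rni_iron=6.0)
        sol = dp.best_diet(problem)
        assert sol.objective == pytest.approx(4.0 / 6.0, abs=1e-6)

    def test_zero_nutrient_foods_give_t_zero(self):
        problem = make_problem([100 / 7, 50 / 7], [0.0, 0.0], [0, 0],
                               [7, 14], (100.0, 100.0), iron_only=False)
        sol = dp.best_diet(problem)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_default_region_best_diet_is_isocaloric(self, default_models):
        within, _ = default_models
        res = within.fit()
        assert res.optimal
        target = within.params.energy_target_kcal_day
        tol = within.cfg.energy_tolerance
        assert abs(res.solution.energy_kcal_day - target) <= (
            target * tol + 1e-4)
        assert "Nutritionally best diet" in res.summary()

    def test_breastmilk_fixed_in_solution(self, default_models):
        within, _ = default_models
        res = within.fit()
        assert res.servings[dp.BREASTMILK] == pytest.approx(7.0, abs=1e-6)


class TestBuildProblem:
    def test_cardinality_and_fixed_breastmilk(self, default_models):
        within, _ = default_models
        problem = within.problem
        assert problem.n_foods == len(within.params.foods)
        i = problem.food_ids.index(dp.BREASTMILK)
        assert problem.lower[i] == problem.upper[i] == 7.0

    def test_missing_composition_row_is_named(self, default_models, toy_fct):
        within, _ = default_models
        with pytest.raises(dp.core.ConfigurationError) as err:
            dp.build_problem(within.params, toy_fct)
        assert "food_" in str(err.value)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def grid_search(problem, sense, step=0.05):
    """Dense grid search over the box, filtered by the energy window."""
    axes = [np.round(np.arange(lo, hi + step / 2, step), 10)
            for lo, hi in zip(problem.lower, problem.upper)]
    mesh = np.meshgrid(*axes, indexing="ij", sparse=True)
    energy = sum(c * m for c, m in zip(problem.energy_coef, mesh))
    e_lo = problem.energy_target * (1 - problem.energy_tolerance)
    e_hi = problem.energy_target * (1 + problem.energy_tolerance)
    feasible = (energy >= e_lo - 1e-9) & (energy <= e_hi + 1e-9)
    obj = sum(c * m for c, m in zip(problem.nutrient_coef[IRON], mesh))
    obj = np.broadcast_to(obj, feasible.shape)
    vals = obj[feasible]
    assert vals.size, "grid found no feasible point"
    return float(vals.max() if sense == "max" else vals.min())


def random_grid_aligned_problem(rng):
    """Random problem whose optimal vertices lie on the 0.05 grid.

    Box bounds are integers, energy coefficients divide 100, and the energy
    window bounds are multiples of 5, so any vertex coordinate
    (E - sum c_i b_i) / c_j is a multiple of 0.05.
    """
    n = int(rng.integers(2, 5))
    hi_cap = {2: 7, 3: 5, 4: 2}[n]
    upper = rng.integers(1, hi_cap + 1, size=n).astype(float)
    lower = np.zeros(n)
    coefs = rng.choice([10.0, 20.0, 25.0, 50.0, 100.0], size=n)
    iron = rng.uniform(0.1, 3.0, size=n)
    e_min, e_max = float(coefs @ lower), float(coefs @ upper)
    grid5 = np.arange(np.ceil(e_min / 5) * 5, e_max + 1e-9, 5.0)
    w = np.sort(rng.choice(grid5, size=2, replace=True))
    return make_problem(coefs, iron, lower, upper, (w[0], w[1]))


def vertex_enumeration(problem, sense):
    """Exact LP oracle: enumerate basic feasible solutions.

    Every vertex activates n linearly independent constraint boundaries;
    solve each candidate system, keep the feasible ones, take the best.
    """
    n = problem.n_foods
    rows, bnds = [], []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(e)
        bnds.append((problem.lower[i], problem.upper[i]))
    for sg, idx in problem.subgroup_members.items():
        a = np.zeros(n)
        a[idx] = 1.0
        rows.append(a)
        bnds.append(problem.subgroup_bounds[sg])
    e_lo = problem.energy_target * (1 - problem.energy_tolerance)
    e_hi = problem.energy_target * (1 + problem.energy_tolerance)
    rows.append(problem.energy_coef)
    bnds.append((e_lo, e_hi))

    def feasible(x):
        for a, (lo, hi) in zip(rows, bnds):
            v = a @ x
            if v < lo - 1e-7 or v > hi + 1e-7:
                return False
        return True

    best = None
    c = problem.nutrient_coef[IRON]
    for combo in itertools.combinations(range(len(rows)), n):
        A = np.array([rows[i] for i in combo])
        if abs(np.linalg.det(A)) < 1e-10:
            continue
        for sides in itertools.product(range(2), repeat=n):
            b = np.array([bnds[i][s] for i, s in zip(combo, sides)])
            x = np.linalg.solve(A, b)
            if feasible(x):
                v = float(c @ x)
                if best is None:
                    best = v
                elif sense == "max":
                    best = max(best, v)
                else:
                    best = min(best, v)
    return best


class TestOracles:
    def test_grid_oracle_on_aligned_problems(self):
        """Solver optima match 0.05-step grid search on 30 random problems
        (the full 200-problem sweep runs with the acceptance checks)."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            problem = random_grid_aligned_problem(rng)
            for sense in ("max", "min"):
                sol = dp.extreme_nutrient_diet(problem, "iron", sense)
                assert sol.optimal
                expected = grid_search(problem, sense)
                tol = max(5e-3 * abs(expected), 1e-3)
                assert abs(sol.objective - expected) <= tol

    def test_vertex_oracle_with_binding_subgroups(self):
        """Exact vertex enumeration agrees on problems with binding
        subgroup constraints (structures the grid family avoids)."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 4))
            upper = rng.uniform(1, 6, size=n)
            lower = np.zeros(n)
            coefs = rng.uniform(8, 60, size=n)
            iron = rng.uniform(0.1, 3.0, size=n)
            e_max = float(coefs @ upper)
            w = np.sort(rng.uniform(0.2 * e_max, 0.9 * e_max, size=2))
            k = int(rng.integers(1, n + 1))
            sg_hi = float(rng.uniform(0.3, 1.0) * upper[:k].sum())
            problem = make_problem(
                coefs, iron, lower, upper, (w[0], w[1]),
                subgroups={"sg_a": list(range(k)),
                           "sg_b": list(range(k, n))} if k < n
                else {"sg_a": list(range(k))},
                subgroup_bounds=None)
            problem.subgroup_bounds = {sg: (0.0, sg_hi if sg == "sg_a"
                                            else float(upper[k:].sum()))
                                       for sg in problem.subgroup_members}
            for sense in ("max", "min"):
                sol = dp.extreme_nutrient_diet(problem, "iron", sense)
                expected = vertex_enumeration(problem, sense)
                if expected is None:
                    assert not sol.optimal
                    continue
                assert sol.optimal
                assert sol.objective == pytest.approx(expected, rel=5e-3,
                                                      abs=1e-3)

    def test_bound_monotonicity(self):
        """Raising a lower bound cannot decrease a minimized objective;
        relaxing an upper bound cannot decrease a maximized one."""
        import copy

        rng = np.random.default_rng(3)
        for _ in range(10):
            problem = random_grid_aligned_problem(rng)
            mn = dp.extreme_nutrient_diet(problem, "iron", "min")
            mx = dp.extreme_nutrient_diet(problem, "iron", "max")

            raised = copy.deepcopy(problem)
            raised.lower = raised.lower.copy()
            raised.lower[0] = min(raised.lower[0] + 1.0, raised.upper[0])
            mn2 = dp.extreme_nutrient_diet(raised, "iron", "min")
            if mn2.optimal and mn.optimal:
                assert mn2.objective >= mn.objective - 1e-7

            relaxed = copy.deepcopy(problem)
            relaxed.upper = relaxed.upper.copy()
            relaxed.upper[0] += 1.0
            relaxed.subgroup_bounds = {
                sg: (lo, hi + 1.0)
                for sg, (lo, hi) in relaxed.subgroup_bounds.items()}
            mx2 = dp.extreme_nutrient_diet(relaxed, "iron", "max")
            if mx2.optimal and mx.optimal:
                assert mx2.objective >= mx.objective - 1e-7
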