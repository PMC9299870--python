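"""Linear-programming diet engine: feasibility, best diet, nutrient extremes.

The decision variables are continuous weekly servings of each food on the
food list.  A diet must keep daily energy within a small tolerance of the
child's requirement (isocaloric constraint), respect food-level serving
limits, and keep weekly servings per food subgroup and food group within the
observed 10th-90th percentile range.  Three analyses mirror the classic
three-module layout of diet-optimization practice:

* module 1 — parameter feasibility: can any diet satisfy all constraints?
* module 2 — the "nutritionally best" diet.  Within the average food
  pattern (group totals pulled toward their median goals by minimizing the
  maximum absolute deviation, then capping it), maximize the worst
  nutrient's share of its RNI capped at 100%, then lexicographically
  maximize the sum of capped shares.  The maximin-with-refinement objective
  is this package's reconstruction of "nutritionally best"; it is an
  interpretation, not a claim of equivalence with any released software.
* module 3 — per-nutrient maximized and minimized diets, optionally with a
  set of food-based recommendations (FBRs) forced by raising chosen
  subgroups' lower bounds to their upper bounds.

All solves use ``scipy.optimize.linprog`` (HiGHS).  Variable order is fixed
(food-list order, auxiliaries after), making objective values reproducible
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import (
    NUTRIENTS,
    AnalysisConfig,
    ConfigurationError,
    FoodCompositionTable,
    NutrientReference,
)
from .params import ModelParameters

__all__ = [
    "LinearDietProblem",
    "DietSolution",
    "FeasibilityReport",
    "build_problem",
    "check_feasibility",
    "best_diet",
    "extreme_nutrient_diet",
    "DietModel",
    "DietResults",
]

_FEAS_EPS = 1e-6  # constraint satisfaction check on reported solutions


@dataclass
class LinearDietProblem:
    """A fully assembled diet LP (data only; solves live in the functions)."""

    food_ids: list[str]
    portions: np.ndarray          # g/day per serving, per food
    energy_coef: np.ndarray       # kcal/day per weekly serving
    nutrient_coef: np.ndarray     # 13 x n, nutrient/day per weekly serving
    lower: np.ndarray             # food-level weekly serving bounds
    upper: np.ndarray
    subgroup_members: dict[str, list[int]]
    subgroup_bounds: dict[str, tuple[float, float]]
    group_members: dict[str, list[int]]
    group_bounds: dict[str, tuple[float, float]]
    group_goals: dict[str, float]
    energy_target: float
    energy_tolerance: float
    mode: str                     # "within_pattern" | "free_pattern"
    rni: np.ndarray = field(default_factory=lambda: np.array([]))
    #: boolean mask over NUTRIENTS: which nutrients carry adequacy goals
    #: (all by default; toy problems may model a single nutrient)
    active: np.ndarray | None = None

    def active_nutrients(self) -> np.ndarray:
        if self.active is None:
            return np.ones(len(NUTRIENTS), dtype=bool)
        return self.active

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    def nutrient_index(self, nutrient: str) -> int:
        return NUTRIENTS.index(nutrient)

    def daily_nutrients(self, servings: np.ndarray) -> pd.Series:
        return pd.Series(self.nutrient_coef @ servings, index=list(NUTRIENTS))

    def daily_energy(self, servings: np.ndarray) -> float:
        return float(self.energy_coef @ servings)


@dataclass
class DietSolution:
    status: str                   # "optimal" | "infeasible" | "unbounded"
    servings: pd.Series | None
    nutrient_totals: pd.Series | None
    percent_rni: pd.Series | None
    objective: float | None
    energy_kcal_day: float | None = None
    detail: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FeasibilityReport:
    feasible: bool
    energy_range: tuple[float, float] | None
    diagnostics: list[str]


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------


def build_problem(params: ModelParameters, fct: FoodCompositionTable,
                  references: NutrientReference | None = None,
                  mode: str = "within_pattern",
                  cfg: AnalysisConfig | None = None) -> LinearDietProblem:
    """Assemble the LP from model parameters and a composition table."""
    if mode not in ("within_pattern", "free_pattern"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    references = references or NutrientReference()
    cfg = cfg or AnalysisConfig()
    missing = [f.food_id for f in params.foods if f.food_id not in fct]
    if missing:
        raise ConfigurationError(
            f"foods lacking composition rows: {missing}"
        )
    food_ids = params.food_ids
    n = len(food_ids)
    portions = np.array([f.portion_g_per_day for f in params.foods])
    lower = np.array([f.min_servings_week for f in params.foods])
    upper = np.array([f.max_servings_week for f in params.foods])
    comp = np.array(
        [fct.row(f).loc[list(NUTRIENTS)].to_numpy(dtype=float)
         for f in food_ids]
    ).T  # 13 x n
    energy100 = np.array([fct.energy_per_100g(f) for f in food_ids])
    # one weekly serving contributes portion/7 grams per day
    per_day_g = portions / 7.0
    energy_coef = per_day_g * energy100 / 100.0
    nutrient_coef = comp * per_day_g / 100.0

    sg_members: dict[str, list[int]] = {}
    for i, f in enumerate(food_ids):
        sg_members.setdefault(params.subgroup_of[f], []).append(i)
    g_members: dict[str, list[int]] = {}
    for sg, idx in sg_members.items():
        g_members.setdefault(params.group_of_subgroup[sg], []).extend(idx)

    rni = np.array([references.rni[n_] for n_ in NUTRIENTS])
    return LinearDietProblem(
        food_ids=food_ids, portions=portions, energy_coef=energy_coef,
        nutrient_coef=nutrient_coef, lower=lower, upper=upper,
        subgroup_members=sg_members,
        subgroup_bounds={sg: params.subgroup_bounds[sg] for sg in sg_members},
        group_members=g_members,
        group_bounds={g: params.group_bounds[g] for g in g_members},
        group_goals={g: params.group_goals[g] for g in g_members
                     if g in params.group_goals},
        energy_target=params.energy_target_kcal_day,
        energy_tolerance=cfg.energy_tolerance,
        mode=mode, rni=rni,
    )


def _aggregate_rows(problem: LinearDietProblem, n_aux: int,
                    fbr_floors: Iterable[str] = ()
                    ) -> tuple[list[np.ndarray], list[float]]:
    """Inequality rows (A x <= b) for subgroup/group bounds and FBR floors."""
    floors = set(fbr_floors)
    unknown = floors - set(problem.subgroup_members)
    if unknown:
        raise ConfigurationError(f"FBR floors on unmodeled subgroups: "
                                 f"{sorted(unknown)}")
    n = problem.n_foods
    rows, rhs = [], []

    def add(indices: Sequence[int], lo: float, hi: float) -> None:
        row = np.zeros(n + n_aux)
        row[list(indices)] = 1.0
        rows.append(row)
        rhs.append(hi)
        rows.append(-row)
        rhs.append(-lo)

    for sg, idx in problem.subgroup_members.items():
        lo, hi = problem.subgroup_bounds[sg]
        if sg in floors:
            lo = hi
        add(idx, lo, hi)
    for g, idx in problem.group_members.items():
        lo, hi = problem.group_bounds[g]
        add(idx, lo, hi)
    return rows, rhs


def _energy_rows(problem: LinearDietProblem, n_aux: int
                 ) -> tuple[list[np.ndarray], list[float]]:
    e = np.concatenate([problem.energy_coef, np.zeros(n_aux)])
    lo = problem.energy_target * (1 - problem.energy_tolerance)
    hi = problem.energy_target * (1 + problem.energy_tolerance)
    return [e, -e], [hi, -lo]


def _solve(c: np.ndarray, A_ub: list[np.ndarray], b_ub: list[float],
           bounds: list[tuple[float, float]]):
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    return res


def _solution_from(problem: LinearDietProblem, x: np.ndarray,
                   objective: float, detail: str = "") -> DietSolution:
    totals = problem.daily_nutrients(x)
    pct = 100.0 * totals.to_numpy() / problem.rni
    return DietSolution(
        status="optimal",
        servings=pd.Series(x, index=problem.food_ids, name="servings_week"),
        nutrient_totals=totals,
        percent_rni=pd.Series(pct, index=list(NUTRIENTS)),
        objective=float(objective),
        energy_kcal_day=problem.daily_energy(x),
        detail=detail,
    )


def _failed(status_code: int, detail: str = "") -> DietSolution:
    status = {2: "infeasible", 3: "unbounded"}.get(status_code, "infeasible")
    return DietSolution(status=status, servings=None, nutrient_totals=None,
                        percent_rni=None, objective=None, detail=detail)


# ---------------------------------------------------------------------------
# module 1 — feasibility diagnostics
# ---------------------------------------------------------------------------


def check_feasibility(problem: LinearDietProblem) -> FeasibilityReport:
    """Solve min/max daily energy under the non-energy constraints and check
    whether the target energy window intersects the achievable range.

    Structural contradictions (inverted bounds; a subgroup minimum exceeding
    the sum of its members' maxima) are named in the diagnostics.
    """
    diagnostics: list[str] = []
    for i, f in enumerate(problem.food_ids):
        if problem.lower[i] > problem.upper[i]:
            diagnostics.append(f"food {f}: min {problem.lower[i]} > max "
                               f"{problem.upper[i]}")
    for level, members, bnds in (
        ("subgroup", problem.subgroup_members, problem.subgroup_bounds),
        ("group", problem.group_members, problem.group_bounds),
    ):
        for key, idx in members.items():
            lo, hi = bnds[key]
            if lo > hi:
                diagnostics.append(f"{level} {key}: min {lo} > max {hi}")
            cap = float(problem.upper[idx].sum())
            if lo > cap + _FEAS_EPS:
                diagnostics.append(
                    f"{level} {key}: min {lo} exceeds sum of member food "
                    f"maxima {cap}"
                )
            floor = float(problem.lower[idx].sum())
            if floor > hi + _FEAS_EPS:
                diagnostics.append(
                    f"{level} {key}: member food minima {floor} exceed max {hi}"
                )
    if diagnostics:
        return FeasibilityReport(False, None, diagnostics)

    rows, rhs = _aggregate_rows(problem, 0)
    bounds = list(zip(problem.lower, problem.upper))
    c = problem.energy_coef
    lo_res = _solve(c, rows, rhs, bounds)
    hi_res = _solve(-c, rows, rhs, bounds)
    if lo_res.status != 0 or hi_res.status != 0:
        return FeasibilityReport(
            False, None, ["non-energy constraints are jointly infeasible"]
        )
    e_min, e_max = float(lo_res.fun), float(-hi_res.fun)
    window = (problem.energy_target * (1 - problem.energy_tolerance),
              problem.energy_target * (1 + problem.energy_tolerance))
    feasible = e_min <= window[1] + _FEAS_EPS and e_max >= window[0] - _FEAS_EPS
    if not feasible:
        diagnostics.append(
            f"energy unreachable: achievable {e_min:.1f}-{e_max:.1f} "
            f"kcal/day, target window {window[0]:.1f}-{window[1]:.1f}"
        )
    return FeasibilityReport(feasible, (e_min, e_max), diagnostics)


# ---------------------------------------------------------------------------
# module 2 — nutritionally best diet
# ---------------------------------------------------------------------------


def _pattern_deviation_cap(problem: LinearDietProblem) -> float:
    """Stage 1: minimize the maximum absolute deviation of group servings
    from the group goals (goal programming), returning the optimum D*."""
    n = problem.n_foods
    goals = problem.group_goals
    rows, rhs = _aggregate_rows(problem, 1)
    e_rows, e_rhs = _energy_rows(problem, 1)
    rows += e_rows
    rhs += e_rhs
    for g, goal in goals.items():
        row = np.zeros(n + 1)
        row[problem.group_members[g]] = 1.0
        row[-1] = -1.0
        rows.append(row.copy())          #  sum - D <= goal
        rhs.append(goal)
        row = np.zeros(n + 1)
        row[problem.group_members[g]] = -1.0
        row[-1] = -1.0
        rows.append(row)                 # -sum - D <= -goal
        rhs.append(-goal)
    c = np.zeros(n + 1)
    c[-1] = 1.0
    bounds = list(zip(problem.lower, problem.upper)) + [(0, None)]
    res = _solve(c, rows, rhs, bounds)
    if res.status != 0:
        raise _InfeasibleStage(res.status, "pattern-deviation stage")
    return float(res.fun)


class _InfeasibleStage(Exception):
    def __init__(self, status_code: int, stage: str):
        self.status_code = status_code
        self.stage = stage


def _base_rows(problem: LinearDietProblem, n_aux: int,
               fbr_floors: Iterable[str] = (),
               deviation_cap: float | None = None
               ) -> tuple[list[np.ndarray], list[float]]:
    rows, rhs = _aggregate_rows(problem, n_aux, fbr_floors)
    e_rows, e_rhs = _energy_rows(problem, n_aux)
    rows += e_rows
    rhs += e_rhs
    if deviation_cap is not None:
        n = problem.n_foods
        for g, goal in problem.group_goals.items():
            row = np.zeros(n + n_aux)
            row[problem.group_members[g]] = 1.0
            rows.append(row)
            rhs.append(goal + deviation_cap + _FEAS_EPS)
            rows.append(-row)
            rhs.append(-(goal - deviation_cap - _FEAS_EPS))
    return rows, rhs


def best_diet(problem: LinearDietProblem,
              references: NutrientReference | None = None) -> DietSolution:
    """Module 2: maximin share of RNIs (capped at 100%), lexicographically
    refined by the sum of capped shares; within-pattern runs first pull the
    food-group totals toward their goals."""
    n = problem.n_foods
    nutr = problem.nutrient_coef
    rni = problem.rni
    cap = None
    try:
        if problem.mode == "within_pattern" and problem.group_goals:
            cap = _pattern_deviation_cap(problem)
    except _InfeasibleStage as exc:
        return _failed(exc.status_code, exc.stage)

    active = np.flatnonzero(problem.active_nutrients())

    # stage 2: maximize t with nutrient_n >= t * RNI_n, t <= 1
    rows, rhs = _base_rows(problem, 1, deviation_cap=cap)
    for k in active:
        row = np.zeros(n + 1)
        row[:n] = -nutr[k]
        row[-1] = rni[k]
        rows.append(row)
        rhs.append(0.0)
    c = np.zeros(n + 1)
    c[-1] = -1.0
    bounds = list(zip(problem.lower, problem.upper)) + [(0.0, 1.0)]
    res = _solve(c, rows, rhs, bounds)
    if res.status != 0:
        return _failed(res.status, "maximin stage")
    t_star = float(res.x[-1])

    # stage 3: fix t*, maximize sum of capped shares y_n
    m = len(active)
    rows, rhs = _base_rows(problem, m, deviation_cap=cap)
    for j, k in enumerate(active):
        row = np.zeros(n + m)
        row[:n] = -nutr[k]
        row[n + j] = rni[k]
        rows.append(row)              # y_k * RNI_k <= nutrient_k
        rhs.append(0.0)
        row = np.zeros(n + m)
        row[:n] = -nutr[k]
        rows.append(row)              # nutrient_k >= t* RNI_k
        rhs.append(-t_star * rni[k] + _FEAS_EPS)
    c = np.zeros(n + m)
    c[n:] = -1.0
    bounds = list(zip(problem.lower, problem.upper)) + [(0.0, 1.0)] * m
    res = _solve(c, rows, rhs, bounds)
    if res.status != 0:
        return _failed(res.status, "refinement stage")
    x = res.x[:n]
    sol = _solution_from(problem, x, objective=t_star,
                         detail=f"t*={t_star:.6f}, sum capped shares="
                                f"{-res.fun:.6f}")
    return sol


# ---------------------------------------------------------------------------
# module 3 — per-nutrient extremes
# ---------------------------------------------------------------------------


def extreme_nutrient_diet(problem: LinearDietProblem, nutrient: str,
                          sense: str,
                          fbr_floors: Iterable[str] = ()) -> DietSolution:
    """Maximize or minimize one nutrient's daily amount under all
    constraints, optionally forcing FBR subgroups to their maxima.

    The minimized diet simulates the low tail of the nutrient's intake
    distribution; the maximized diet (without FBRs) defines problem
    nutrients.  An infeasible forced set yields status "infeasible" — the
    caller records the set as untestable rather than failing.
    """
    if sense not in ("max", "min"):
        raise ConfigurationError(f"sense must be 'max' or 'min', got {sense!r}")
    k = problem.nutrient_index(nutrient)
    rows, rhs = _base_rows(problem, 0, fbr_floors=fbr_floors)
    c = problem.nutrient_coef[k].copy()
    if sense == "max":
        c = -c
    bounds = list(zip(problem.lower, problem.upper))
    res = _solve(c, rows, rhs, bounds)
    if res.status != 0:
        return _failed(res.status, f"{sense} {nutrient}")
    x = res.x
    amount = float(problem.nutrient_coef[k] @ x)
    return _solution_from(problem, x, objective=amount,
                          detail=f"{sense} {nutrient}")


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class DietModel:
    """Diet LP for one survey's parameters, statsmodels-style.

    Parameters
    ----------
    params : ModelParameters
        The survey-derived LP inputs.
    fct : FoodCompositionTable
    references : NutrientReference, optional
    mode : str
        "within_pattern" (default) keeps food-group totals near their goals;
        "free_pattern" uses only the percentile bounds.
    """

    def __init__(self, params: ModelParameters, fct: FoodCompositionTable,
                 references: NutrientReference | None = None,
                 cfg: AnalysisConfig | None = None,
                 mode: str = "within_pattern"):
        self.params = params
        self.fct = fct
        self.references = references or NutrientReference()
        self.cfg = cfg or AnalysisConfig()
        self.mode = mode
        self.problem = build_problem(params, fct, self.references, mode,
                                     self.cfg)

    def check_feasibility(self) -> FeasibilityReport:
        return check_feasibility(self.problem)

    def fit(self) -> "DietResults":
        """Solve the module-2 nutritionally best diet."""
        solution = best_diet(self.problem, self.references)
        return DietResults(self, solution)

    def extreme(self, nutrient: str, sense: str,
                fbr_floors: Iterable[str] = ()) -> DietSolution:
        """Module-3 maximized/minimized diet for one nutrient."""
        return extreme_nutrient_diet(self.problem, nutrient, sense,
                                     fbr_floors)


class DietResults:
    """Fitted module-2 diet with its nutrient profile."""

    def __init__(self, model: DietModel, solution: DietSolution):
        self.model = model
        self.solution = solution

    @property
    def optimal(self) -> bool:
        return self.solution.optimal

    @property
    def servings(self) -> pd.Series:
        return self.solution.servings

    @property
    def percent_rni(self) -> pd.Series:
        return self.solution.percent_rni

    def summary(self) -> str:
        s = self.solution
        lines = [
            "Nutritionally best diet"
            f" ({self.model.mode}, source={self.model.params.source_label})",
            f"status: {s.status}    worst nutrient share t* = "
            f"{s.objective:.3f}" if s.optimal else f"status: {s.status}",
        ]
        if not s.optimal:
            return "\n".join(lines)
        lines.append(f"daily energy: {s.energy_kcal_day:.0f} kcal "
                     f"(target {self.model.params.energy_target_kcal_day:.0f})")
        lines.append("")
        lines.append(f"{'food':28s} {'servings/wk':>11s} {'g/day':>8s}")
        portions = {f.food_id: f.portion_g_per_day
                    for f in self.model.params.foods}
        for food, v in s.servings.items():
            if v > 1e-6:
                lines.append(f"{food:28s} {v:11.2f} "
                             f"{v * portions[food] / 7:8.1f}")
        lines.append("")
        lines.append(f"{'nutrient':14s} {'daily':>10s} {'% RNI':>8s}")
        for n in NUTRIENTS:
            lines.append(f"{n:14s} {s.nutrient_totals[n]:10.2f} "
                         f"{s.percent_rni[n]:8.1f}")
        return "\n".join(lines)
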