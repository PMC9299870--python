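"""Food-based recommendation (FBR) selection from LP diet solutions.

An FBR is a recommended number of weekly servings from a food subgroup.
The pipeline: classify problem nutrients (maximized diet below 100% RNI);
map which subgroups are good sources (supplying at least 5% of a nutrient in
the best diet); rank up to eight candidate subgroups by how many nutrients
they supply; enumerate every combination of two or more candidates (2^k-k-1
sets for k candidates, 247 at the cap of eight); score each set by how many
nutrients its forced minimized diets hold at or above 65% of the RNI; pick
the set with the highest score using the fewest recommendations; and flag
the nutrients still below 65% under the chosen set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    BREASTMILK,
    NUTRIENTS,
    AnalysisConfig,
    ValidationError,
)
from .lp import DietModel, DietSolution, extreme_nutrient_diet

logger = logging.getLogger(__name__)

__all__ = [
    "NutrientAssessment",
    "SourceMap",
    "FbrEvaluation",
    "assess_nutrients",
    "good_sources",
    "candidate_fbrs",
    "enumerate_fbr_sets",
    "evaluate_fbr_sets",
    "select_final",
    "residual_inadequate",
    "run_fbr_pipeline",
    "FbrReport",
]


@dataclass
class NutrientAssessment:
    """Per-nutrient maximized/minimized %RNI without FBRs, and problem flags.

    A problem nutrient is one whose maximized diet content is strictly below
    100% of its RNI (exactly 100% is not a problem).
    """

    maximized_pct: dict[str, float]
    minimized_pct: dict[str, float]
    is_problem: dict[str, bool]

    @property
    def problem_nutrients(self) -> list[str]:
        return [n for n in NUTRIENTS if self.is_problem.get(n)]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "maximized_pct_rni": self.maximized_pct,
            "minimized_pct_rni": self.minimized_pct,
            "is_problem": self.is_problem,
        })


@dataclass
class SourceMap:
    """subgroup -> nutrients it supplies at >= the source threshold of the
    best diet's total, plus the share matrix itself."""

    sources: dict[str, set[str]]
    shares: pd.DataFrame  # subgroups x nutrients, fraction of total
    skipped_nutrients: list[str] = field(default_factory=list)

    def count(self, subgroup: str, universe=NUTRIENTS) -> int:
        return len(self.sources.get(subgroup, set()) & set(universe))

    def counts(self, universe=NUTRIENTS) -> dict[str, int]:
        return {sg: self.count(sg, universe) for sg in self.sources}


@dataclass
class FbrEvaluation:
    subgroups: tuple[str, ...]
    minimized_pct: dict[str, float]
    score: int                      # nutrients at/above the adequacy floor
    feasible: bool = True

    @property
    def size(self) -> int:
        return len(self.subgroups)

    @property
    def summed_pct(self) -> float:
        return sum(self.minimized_pct.values())


# ---------------------------------------------------------------------------


def assess_nutrients(maximized: dict[str, DietSolution],
                     minimized: dict[str, DietSolution],
                     cfg: AnalysisConfig | None = None) -> NutrientAssessment:
    """Classify problem nutrients from the no-FBR module-3 solves."""
    cfg = cfg or AnalysisConfig()
    missing = [n for n in NUTRIENTS if n not in maximized or n not in minimized]
    if missing:
        raise ValidationError(f"missing module-3 solves for: {missing}")
    max_pct, min_pct, problem = {}, {}, {}
    ceiling = cfg.problem_nutrient_ceiling * 100.0
    for n in NUTRIENTS:
        sol = maximized[n]
        if not sol.optimal:
            raise ValidationError(f"maximized solve for {n} not optimal")
        max_pct[n] = float(sol.percent_rni[n])
        msol = minimized[n]
        min_pct[n] = float(msol.percent_rni[n]) if msol.optimal else float("nan")
        problem[n] = max_pct[n] < ceiling - 1e-9
    return NutrientAssessment(max_pct, min_pct, problem)


def good_sources(best: DietSolution, model: DietModel,
                 cfg: AnalysisConfig | None = None) -> SourceMap:
    """Subgroup shares of each nutrient in the best diet.

    A subgroup is a source of nutrient n when its foods jointly supply at
    least ``source_threshold`` (default 5%) of the diet's total n.  Nutrients
    with zero total are skipped with a warning.
    """
    cfg = cfg or AnalysisConfig()
    if not best.optimal:
        raise ValidationError("good_sources requires an optimal best diet")
    problem = model.problem
    x = best.servings.to_numpy()
    contrib = problem.nutrient_coef * x  # 13 x n_foods, daily amounts
    rows = {}
    skipped = []
    totals = contrib.sum(axis=1)
    for sg, idx in problem.subgroup_members.items():
        rows[sg] = contrib[:, idx].sum(axis=1)
    shares = pd.DataFrame(rows, index=list(NUTRIENTS)).T
    for k, n in enumerate(NUTRIENTS):
        if totals[k] <= 0:
            skipped.append(n)
            logger.warning("nutrient %s has zero total in best diet; "
                           "skipped from source map", n)
            shares[n] = 0.0
        else:
            shares[n] = shares[n] / totals[k]
    sources = {
        sg: {n for n in NUTRIENTS
             if n not in skipped
             and shares.at[sg, n] >= cfg.source_threshold - 1e-12}
        for sg in shares.index
    }
    return SourceMap(sources=sources, shares=shares,
                     skipped_nutrients=skipped)


def candidate_fbrs(source_map: SourceMap,
                   cfg: AnalysisConfig | None = None) -> list[str]:
    """Rank subgroups by the number of nutrients they are good sources of.

    Ties break by total summed share (descending), then subgroup label
    (ascending).  Breastmilk is excluded — it is fixed at seven weekly
    servings in every diet, so forcing it is vacuous.  At most
    ``max_fbr_candidates`` (default 8) subgroups are returned; fewer than
    two is an error because no sets could be tested.
    """
    cfg = cfg or AnalysisConfig()
    universe = cfg.source_count_nutrients
    entries = []
    for sg in source_map.sources:
        if sg == BREASTMILK:
            continue
        count = source_map.count(sg, universe)
        if count == 0:
            continue
        total_share = float(source_map.shares.loc[sg, list(universe)].sum())
        entries.append((-count, -total_share, sg))
    entries.sort()
    ranked = [sg for _, _, sg in entries[: cfg.max_fbr_candidates]]
    if len(ranked) < 2:
        raise ValidationError(
            f"only {len(ranked)} candidate subgroups; need at least 2"
        )
    return ranked


def enumerate_fbr_sets(candidates: list[str]) -> list[tuple[str, ...]]:
    """All subsets of two or more candidates: 2^k - k - 1 sets for k of them.

    Singletons are excluded; with the cap of eight candidates this yields the
    familiar 247 testable combinations.
    """
    k = len(candidates)
    if not 2 <= k <= 8:
        raise ValidationError(f"need 2-8 candidates, got {k}")
    sets = []
    for size in range(2, k + 1):
        sets.extend(itertools.combinations(candidates, size))
    return sets


def evaluate_fbr_sets(model: DietModel,
                      sets: list[tuple[str, ...]],
                      cfg: AnalysisConfig | None = None
                      ) -> list[FbrEvaluation]:
    """Score every FBR set: minimized %RNI per nutrient under forcing.

    Infeasible forced sets are recorded (feasible=False) and skipped by
    selection, not fatal — percentile-bound floors can conflict with the
    energy window.
    """
    cfg = cfg or AnalysisConfig()
    floor = cfg.rni_adequacy_floor * 100.0
    out = []
    for subgroups in sets:
        min_pct = {}
        feasible = True
        for n in NUTRIENTS:
            sol = model.extreme(n, "min", fbr_floors=subgroups)
            if not sol.optimal:
                feasible = False
                logger.info("FBR set %s infeasible (%s)", subgroups, n)
                break
            min_pct[n] = float(sol.percent_rni[n])
        score = sum(1 for v in min_pct.values() if v >= floor - 1e-9)
        out.append(FbrEvaluation(tuple(subgroups), min_pct,
                                 score if feasible else 0, feasible))
    return out


def select_final(evaluations: list[FbrEvaluation]) -> FbrEvaluation:
    """Pick the set holding the most nutrients at/above the floor with the
    fewest recommendations; ties break by summed minimized %RNI (descending)
    then label (ascending)."""
    feasible = [e for e in evaluations if e.feasible]
    if not feasible:
        raise ValidationError("no feasible FBR sets to select from")
    return min(
        feasible,
        key=lambda e: (-e.score, e.size, -e.summed_pct, e.subgroups),
    )


def residual_inadequate(final_eval: FbrEvaluation,
                        cfg: AnalysisConfig | None = None) -> list[str]:
    """Nutrients whose minimized %RNI stays below the floor under the final
    set (at exactly the floor counts as met)."""
    cfg = cfg or AnalysisConfig()
    floor = cfg.rni_adequacy_floor * 100.0
    return [n for n in NUTRIENTS
            if final_eval.minimized_pct.get(n, float("nan")) < floor - 1e-9]


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------


@dataclass
class FbrReport:
    assessment: NutrientAssessment
    source_map: SourceMap
    candidates: list[str]
    evaluations: list[FbrEvaluation]
    final: FbrEvaluation
    residual: list[str]

    def to_dict(self) -> dict:
        return {
            "problem_nutrients": self.assessment.problem_nutrients,
            "maximized_pct_rni": self.assessment.maximized_pct,
            "minimized_pct_rni": self.assessment.minimized_pct,
            "source_counts": {sg: sorted(ns) for sg, ns
                              in self.source_map.sources.items()},
            "candidates": self.candidates,
            "n_sets_tested": len(self.evaluations),
            "evaluations": [
                {"subgroups": list(e.subgroups), "score": e.score,
                 "feasible": e.feasible,
                 "minimized_pct_rni": e.minimized_pct}
                for e in self.evaluations
            ],
            "final_set": list(self.final.subgroups),
            "final_score": self.final.score,
            "residual_inadequate": self.residual,
        }


def run_fbr_pipeline(within_model: DietModel, free_model: DietModel,
                     cfg: AnalysisConfig | None = None) -> FbrReport:
    """Modules 2-3 plus selection, for one survey's parameters.

    ``within_model`` (group goals active) supplies the best diet for the
    source map; ``free_model`` (percentile bounds only) supplies the
    per-nutrient extremes and the FBR-forced minimized diets.
    """
    cfg = cfg or AnalysisConfig()
    best = within_model.fit().solution
    if not best.optimal:
        raise ValidationError("module-2 best diet infeasible; check module 1")
    maximized = {n: free_model.extreme(n, "max") for n in NUTRIENTS}
    minimized = {n: free_model.extreme(n, "min") for n in NUTRIENTS}
    assessment = assess_nutrients(maximized, minimized, cfg)
    source_map = good_sources(best, within_model, cfg)
    candidates = candidate_fbrs(source_map, cfg)
    sets = enumerate_fbr_sets(candidates)
    evaluations = evaluate_fbr_sets(free_model, sets, cfg)
    final = select_final(evaluations)
    residual = residual_inadequate(final, cfg)
    return FbrReport(assessment, source_map, candidates, evaluations,
                     final, residual)
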