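"""Turn a consumption survey into linear-programming model parameters.

The LP inputs are: a food list (foods consumed by at least 5% of eligible
households for an HCES, or of children for a 24HR survey, excluding
non-nutritive items and — for household data — foods inappropriate for young
children, with breastmilk always included); a median daily portion per food
over its consumers; food-level weekly serving limits from a consumer-fraction
policy table; 10th/90th-percentile weekly-serving bounds per food subgroup
and group; 50th-percentile group goals; and the child's daily energy
requirement as the isocaloric target.

Percentiles are nearest-rank throughout (the value at position
``ceil(p/100 * n)`` of the ascending sort), which is deterministic on small
samples and needs no interpolation convention.  HCES and 24HR parameter
generation share all code paths except the consumer-fraction denominator and
the grams-per-week derivation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import ame
from .core import (
    BREASTMILK,
    AnalysisConfig,
    ConfigurationError,
    FoodTaxonomy,
    NutrientReference,
    SurveyDataset,
    ValidationError,
)

__all__ = [
    "FoodParameter",
    "ModelParameters",
    "child_intake_table",
    "build_food_list",
    "median_portion",
    "nearest_rank",
    "servings_per_week",
    "aggregate_bounds",
    "food_serving_limits",
    "generate_parameters",
]


@dataclass
class FoodParameter:
    food_id: str
    portion_g_per_day: float
    min_servings_week: float
    max_servings_week: float
    consumer_fraction: float

    def __post_init__(self) -> None:
        if self.portion_g_per_day <= 0:
            raise ConfigurationError(
                f"food {self.food_id}: portion must be positive"
            )
        if self.min_servings_week > self.max_servings_week:
            raise ConfigurationError(
                f"food {self.food_id}: min servings exceed max"
            )


@dataclass
class ModelParameters:
    """Complete LP inputs derived from one survey."""

    foods: list[FoodParameter]
    subgroup_bounds: dict[str, tuple[float, float]]
    group_bounds: dict[str, tuple[float, float]]
    group_goals: dict[str, float]
    energy_target_kcal_day: float
    source_label: str  # "hces" | "recall24h"
    subgroup_of: dict[str, str] = field(default_factory=dict)
    group_of_subgroup: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.energy_target_kcal_day <= 0:
            raise ConfigurationError("energy target must be positive")
        for f in self.foods:
            sg = self.subgroup_of.get(f.food_id)
            if sg is None or sg not in self.subgroup_bounds:
                raise ConfigurationError(
                    f"food {f.food_id} lacks subgroup bounds"
                )
            if self.group_of_subgroup.get(sg) not in self.group_bounds:
                raise ConfigurationError(
                    f"subgroup {sg} lacks group bounds"
                )

    @property
    def food_ids(self) -> list[str]:
        return [f.food_id for f in self.foods]

    def food(self, food_id: str) -> FoodParameter:
        for f in self.foods:
            if f.food_id == food_id:
                return f
        raise KeyError(food_id)

    def max_weekly_grams(self) -> pd.Series:
        """Maximum modeled weekly grams per food (max servings x portion)."""
        return pd.Series(
            {f.food_id: f.max_servings_week * f.portion_g_per_day
             for f in self.foods}
        )

    def to_json(self, path: str) -> None:
        payload = {
            "schema_version": 1,
            "source_label": self.source_label,
            "energy_target_kcal_day": self.energy_target_kcal_day,
            "foods": [asdict(f) for f in self.foods],
            "subgroup_bounds": {k: list(v) for k, v in self.subgroup_bounds.items()},
            "group_bounds": {k: list(v) for k, v in self.group_bounds.items()},
            "group_goals": self.group_goals,
            "subgroup_of": self.subgroup_of,
            "group_of_subgroup": self.group_of_subgroup,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "ModelParameters":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            foods=[FoodParameter(**f) for f in payload["foods"]],
            subgroup_bounds={k: tuple(v) for k, v in payload["subgroup_bounds"].items()},
            group_bounds={k: tuple(v) for k, v in payload["group_bounds"].items()},
            group_goals=payload["group_goals"],
            energy_target_kcal_day=payload["energy_target_kcal_day"],
            source_label=payload["source_label"],
            subgroup_of=payload["subgroup_of"],
            group_of_subgroup=payload["group_of_subgroup"],
        )

    def to_frame(self) -> pd.DataFrame:
        """Human-readable per-food parameter table."""
        rows = []
        for f in self.foods:
            sg = self.subgroup_of[f.food_id]
            rows.append({
                "food_id": f.food_id, "subgroup_id": sg,
                "group_id": self.group_of_subgroup[sg],
                "portion_g_per_day": f.portion_g_per_day,
                "min_servings_week": f.min_servings_week,
                "max_servings_week": f.max_servings_week,
                "consumer_fraction": f.consumer_fraction,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intake tables and consumer fractions
# ---------------------------------------------------------------------------


def child_intake_table(dataset: SurveyDataset,
                       references: NutrientReference,
                       cfg: AnalysisConfig) -> tuple[pd.DataFrame, int]:
    """Child-level daily intakes (child_id, food_id, g_per_day) and the
    consumer-fraction denominator.

    For a 24HR survey the records are already child-level; the denominator is
    the number of 12-23-month-old children.  For an HCES the household
    records are AME-redistributed to each eligible household's index child;
    the denominator is the number of eligible households (those with a
    12-23-month-old child, or under-five children when configured).
    """
    if dataset.kind == "recall24h":
        intakes = (
            dataset.records.groupby(["child_id", "food_id"], as_index=False)
            ["quantity_g"].sum()
            .rename(columns={"quantity_g": "g_per_day"})
        )
        ages = dataset.roster
        kids = ages[(ages["age_months"] >= 12) & (ages["age_months"] < 24)]
        denominator = kids["person_id"].nunique() or intakes["child_id"].nunique()
        return intakes, int(denominator)
    intakes = ame.redistribute_dataset(dataset, references, cfg)
    eligible = dataset.eligible_households(under5=cfg.hces_denominator_under5)
    denominator = len(eligible)
    return intakes[["child_id", "food_id", "g_per_day"]], int(denominator)


def _consumer_fractions(intakes: pd.DataFrame, denominator: int) -> pd.Series:
    consuming = intakes[intakes["g_per_day"] > 0]
    counts = consuming.groupby("food_id")["child_id"].nunique()
    return counts / denominator


# ---------------------------------------------------------------------------
# food list
# ---------------------------------------------------------------------------


def build_food_list(dataset: SurveyDataset, taxonomy: FoodTaxonomy,
                    cfg: AnalysisConfig | None = None,
                    references: NutrientReference | None = None,
                    intakes: pd.DataFrame | None = None,
                    denominator: int | None = None) -> list[str]:
    """Foods consumed by at least the threshold fraction of units.

    Units are eligible households (HCES) or children (24HR).  Non-nutritive
    items (water, tea, condiments) are excluded from both kinds; items not
    typically consumed by young children (e.g. alcoholic beverages) are
    excluded from HCES lists.  Breastmilk is always included.
    """
    cfg = cfg or AnalysisConfig()
    references = references or NutrientReference()
    if intakes is None or denominator is None:
        intakes, denominator = child_intake_table(dataset, references, cfg)
    if denominator == 0:
        raise ValidationError("no eligible units to compute consumer fractions")
    fractions = _consumer_fractions(intakes, denominator)
    keep = []
    for food_id, frac in fractions.items():
        if frac < cfg.food_list_threshold:
            continue
        if food_id not in taxonomy:
            continue  # unresolved foods are surfaced by validate_pair
        row = taxonomy.table.loc[food_id]
        if not row["is_nutritive"]:
            continue
        if dataset.kind == "hces" and not row["child_appropriate"]:
            continue
        keep.append(food_id)
    keep = sorted(set(keep) - {BREASTMILK})
    # breastmilk is always modeled, so the list is never empty
    return keep + [BREASTMILK]


# ---------------------------------------------------------------------------
# portions and servings
# ---------------------------------------------------------------------------


def nearest_rank(values, p: float) -> float:
    """Nearest-rank percentile: sorted value at position ceil(p/100 * n)."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise ValidationError("percentile of empty sample")
    k = max(1, math.ceil(p / 100.0 * arr.size))
    return float(arr[k - 1])


def median_portion(intakes: pd.DataFrame, food_id: str) -> float:
    """Nearest-rank median daily grams over the food's consumers (zeros
    excluded).  Breastmilk portions come from
    :func:`dietpair.ame.breastmilk_portion`, not from survey records."""
    grams = intakes.loc[
        (intakes["food_id"] == food_id) & (intakes["g_per_day"] > 0),
        "g_per_day",
    ]
    if grams.empty:
        raise ValidationError(f"food {food_id} has no consumers")
    return nearest_rank(grams, 50)


def servings_per_week(intakes: pd.DataFrame, portions: pd.Series,
                      children: pd.Index) -> pd.DataFrame:
    """Weekly servings per (child, food): weekly grams / daily portion.

    Daily intakes are scaled to a week first (x7).  Non-consumers appear as
    zeros, so the result is a dense children x foods frame.
    """
    if (portions <= 0).any():
        bad = sorted(portions[portions <= 0].index)
        raise ConfigurationError(f"non-positive portions for {bad}")
    table = intakes.pivot_table(index="child_id", columns="food_id",
                                values="g_per_day", aggfunc="sum",
                                fill_value=0.0)
    table = table.reindex(index=children, columns=portions.index,
                          fill_value=0.0)
    return table.mul(7.0).div(portions, axis=1)


def aggregate_bounds(servings: pd.DataFrame, taxonomy: FoodTaxonomy,
                     cfg: AnalysisConfig | None = None) -> tuple[
                         dict[str, tuple[float, float]],
                         dict[str, tuple[float, float]],
                         dict[str, float]]:
    """Subgroup/group (P10, P90) bounds and group P50 goals.

    Percentiles are nearest-rank over all children, non-consumers included
    as zeros (configurable via ``include_nonconsumers``).
    """
    cfg = cfg or AnalysisConfig()
    subgroup_map = {f: taxonomy.subgroup_of(f) for f in servings.columns}
    sg_servings = servings.T.groupby(subgroup_map.get).sum().T
    group_map = {sg: taxonomy.group_of_subgroup(sg)
                 for sg in sg_servings.columns}
    g_servings = sg_servings.T.groupby(group_map.get).sum().T

    def bounds(frame: pd.DataFrame) -> dict[str, tuple[float, float]]:
        out = {}
        for col in frame.columns:
            vals = frame[col]
            if not cfg.include_nonconsumers:
                vals = vals[vals > 0]
                if vals.empty:
                    vals = frame[col]
            out[col] = (nearest_rank(vals, cfg.percentile_low),
                        nearest_rank(vals, cfg.percentile_high))
        return out

    goals = {col: nearest_rank(
        g_servings[col] if cfg.include_nonconsumers
        else (g_servings[col][g_servings[col] > 0]
              if (g_servings[col] > 0).any() else g_servings[col]),
        cfg.percentile_goal)
        for col in g_servings.columns}
    return bounds(sg_servings), bounds(g_servings), goals


def food_serving_limits(consumer_fraction: float,
                        policy=None) -> tuple[float, float]:
    """Look up weekly (min, max) servings from the consumer-fraction policy.

    The policy is an ordered step table of (upper cut-point, min, max) tiers
    with half-open intervals; a fraction on a cut-point belongs to the upper
    tier.  Breastmilk is fixed at (7, 7) upstream and never passes through
    this lookup.
    """
    policy = policy if policy is not None else AnalysisConfig().serving_limit_policy
    cuts = [c for c, _, _ in policy]
    if cuts != sorted(cuts):
        raise ConfigurationError("serving-limit policy cut-points unordered")
    for cut, lo, hi in policy:
        if consumer_fraction < cut:
            return (lo, hi)
    return policy[-1][1], policy[-1][2]


# ---------------------------------------------------------------------------
# full parameter generation
# ---------------------------------------------------------------------------


def generate_parameters(dataset: SurveyDataset, taxonomy: FoodTaxonomy,
                        references: NutrientReference | None = None,
                        cfg: AnalysisConfig | None = None) -> ModelParameters:
    """Run the whole parameter-generation stage for one survey."""
    cfg = cfg or AnalysisConfig()
    references = references or NutrientReference()
    energy_target = references.eer(18, "female")  # 12-23-month band

    intakes, denominator = child_intake_table(dataset, references, cfg)
    food_list = build_food_list(dataset, taxonomy, cfg, references,
                                intakes, denominator)
    fractions = _consumer_fractions(intakes, denominator)

    bm_portion = ame.breastmilk_portion(energy_target, 18, cfg)
    portions = {}
    foods = []
    for food_id in food_list:
        if food_id == BREASTMILK:
            portions[food_id] = bm_portion
            foods.append(FoodParameter(food_id, bm_portion, 7.0, 7.0,
                                       consumer_fraction=1.0))
            continue
        portion = median_portion(intakes, food_id)
        frac = float(fractions.get(food_id, 0.0))
        lo, hi = food_serving_limits(frac, cfg.serving_limit_policy)
        portions[food_id] = portion
        foods.append(FoodParameter(food_id, portion, lo, hi, frac))

    children = pd.Index(
        sorted(intakes["child_id"].unique()), name="child_id"
    )
    portion_series = pd.Series(portions)
    non_bm = portion_series.drop(BREASTMILK)
    servings = servings_per_week(
        intakes[intakes["food_id"].isin(non_bm.index)], non_bm, children
    )
    # every child takes the fixed 7 weekly breastmilk servings
    servings[BREASTMILK] = 7.0

    sg_bounds, g_bounds, goals = aggregate_bounds(servings, taxonomy, cfg)
    sg_bounds[BREASTMILK] = (7.0, 7.0)
    g_bounds[BREASTMILK] = (7.0, 7.0)
    goals[BREASTMILK] = 7.0

    subgroup_of = {f: taxonomy.subgroup_of(f) for f in food_list}
    group_of_subgroup = {sg: taxonomy.group_of_subgroup(sg)
                         for sg in set(subgroup_of.values())}
    return ModelParameters(
        foods=foods,
        subgroup_bounds=sg_bounds,
        group_bounds=g_bounds,
        group_goals=goals,
        energy_target_kcal_day=float(energy_target),
        source_label=dataset.kind,
        subgroup_of=subgroup_of,
        group_of_subgroup=group_of_subgroup,
    )
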