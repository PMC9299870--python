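"""Synthetic paired HCES/24HR surveys drawn from one "true" food environment.

Real paired household-survey and child-recall datasets are proprietary, so
every downstream stage is exercised on synthetic pairs generated here.  A
food environment fixes, per food: its subgroup and group, a true household
consumption propensity, a true child consumption propensity, seasonal
availability months, a log-normal portion-size distribution (adult scale,
grams/day), and a nutrient composition sampled from per-group ranges.

Both survey arms sample from this shared truth, with divergence controlled
by explicit knobs: the fraction of environment foods on the closed HCES
questionnaire, the survey window months of each arm, the HCES recall length
(7 or 14 days), propensity noise, and the sample sizes.  With all knobs at
zero divergence the two arms measure the same environment, which gives the
recovery tests a known answer.

HCES quantities are generated bottom-up: each member's pseudo-intake of a
consumed food is the household's portion draw scaled by the member's
breastmilk-adjusted adult-male-equivalent (AME), and the household total is
their sum over the recall period.  Redistribution therefore has an exact
truth to recover: the index child's true intake is the portion draw times
the child's adjusted AME.

Default propensities are drawn from a mixture of rare foods (below 2.5% of
consumers) and common foods (10-90%), deliberately leaving the neighbourhood
of the 5% food-list threshold empty so that list membership is stable at the
default sample sizes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ame
from .core import (
    BREASTMILK,
    NUTRIENTS,
    AnalysisConfig,
    FoodCompositionTable,
    FoodTaxonomy,
    NutrientReference,
    SurveyDataset,
    ValidationError,
)

__all__ = [
    "EnvironmentSpec",
    "DivergenceKnobs",
    "Environment",
    "generate_environment",
    "generate_hces",
    "generate_recall",
    "write_environment",
]

# (group, subgroup) template the generator assigns foods to, round-robin
# after a seeded shuffle.  Mirrors the subgroup granularity used in
# complementary-feeding diet modeling.
_TEMPLATE: tuple[tuple[str, str], ...] = (
    ("grains", "whole_grains"),
    ("grains", "refined_grains"),
    ("legumes_nuts_seeds", "beans_lentils_peas"),
    ("legumes_nuts_seeds", "nuts_seeds"),
    ("dairy", "milk"),
    ("meat_fish_eggs", "red_meat"),
    ("meat_fish_eggs", "poultry"),
    ("meat_fish_eggs", "fish"),
    ("meat_fish_eggs", "eggs"),
    ("meat_fish_eggs", "organ_meat"),
    ("vegetables", "dark_green_leafy_vegetables"),
    ("vegetables", "vitamin_a_vegetables"),
    ("vegetables", "other_vegetables"),
    ("fruits", "vitamin_a_fruit"),
    ("fruits", "other_fruit"),
    ("starchy_roots", "roots_tubers"),
    ("added_fats", "vegetable_oil"),
    ("added_sugars", "sugar"),
    ("beverages", "sweetened_drinks"),
)
_NONNUTRITIVE_SUBGROUP = ("miscellaneous", "condiments_tea_water")
_INAPPROPRIATE_SUBGROUP = ("beverages", "alcoholic_drinks")

# per-group composition sampling ranges per 100 g edible portion
# (energy kcal, then the 13 nutrients in core.NUTRIENTS order/units)
_COMPOSITION_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "grains": {"energy_kcal": (110, 360), "fat": (0.5, 3), "calcium": (5, 30),
               "folate": (10, 50), "iron": (0.5, 4), "niacin": (1, 5),
               "protein": (2, 10), "riboflavin": (0.02, 0.2),
               "thiamin": (0.05, 0.4), "vitamin_a": (0, 5),
               "vitamin_b12": (0, 0), "vitamin_b6": (0.05, 0.3),
               "vitamin_c": (0, 0), "zinc": (0.5, 2.5)},
    "legumes_nuts_seeds": {"energy_kcal": (100, 380), "fat": (0.5, 30),
               "calcium": (20, 100), "folate": (50, 300), "iron": (1.5, 6),
               "niacin": (0.5, 3), "protein": (5, 22),
               "riboflavin": (0.05, 0.2), "thiamin": (0.1, 0.5),
               "vitamin_a": (0, 5), "vitamin_b12": (0, 0),
               "vitamin_b6": (0.1, 0.4), "vitamin_c": (0, 3),
               "zinc": (1, 3.5)},
    "dairy": {"energy_kcal": (55, 90), "fat": (2.5, 5), "calcium": (95, 135),
               "folate": (3, 10), "iron": (0.02, 0.15), "niacin": (0.05, 0.3),
               "protein": (3, 4.5), "riboflavin": (0.12, 0.3),
               "thiamin": (0.02, 0.06), "vitamin_a": (25, 70),
               "vitamin_b12": (0.3, 0.6), "vitamin_b6": (0.03, 0.08),
               "vitamin_c": (0, 2), "zinc": (0.3, 0.6)},
    "meat_fish_eggs": {"energy_kcal": (100, 260), "fat": (2, 18),
               "calcium": (5, 120), "folate": (2, 200), "iron": (0.8, 9),
               "niacin": (2, 10), "protein": (12, 28),
               "riboflavin": (0.1, 2.5), "thiamin": (0.04, 0.4),
               "vitamin_a": (0, 900), "vitamin_b12": (0.4, 20),
               "vitamin_b6": (0.1, 0.7), "vitamin_c": (0, 5),
               "zinc": (1, 5)},
    "vegetables": {"energy_kcal": (20, 60), "fat": (0.1, 0.8),
               "calcium": (20, 180), "folate": (20, 160), "iron": (0.4, 3.5),
               "niacin": (0.3, 1.5), "protein": (1, 4.5),
               "riboflavin": (0.03, 0.3), "thiamin": (0.03, 0.15),
               "vitamin_a": (0, 700), "vitamin_b12": (0, 0),
               "vitamin_b6": (0.05, 0.3), "vitamin_c": (5, 90),
               "zinc": (0.2, 1)},
    "fruits": {"energy_kcal": (30, 110), "fat": (0.1, 0.5),
               "calcium": (5, 40), "folate": (5, 50), "iron": (0.1, 1),
               "niacin": (0.2, 1), "protein": (0.3, 1.5),
               "riboflavin": (0.02, 0.1), "thiamin": (0.02, 0.1),
               "vitamin_a": (0, 350), "vitamin_b12": (0, 0),
               "vitamin_b6": (0.03, 0.3), "vitamin_c": (5, 70),
               "zinc": (0.05, 0.3)},
    "starchy_roots": {"energy_kcal": (80, 170), "fat": (0.1, 0.5),
               "calcium": (10, 50), "folate": (10, 40), "iron": (0.3, 1.5),
               "niacin": (0.5, 2), "protein": (1, 3),
               "riboflavin": (0.02, 0.08), "thiamin": (0.05, 0.15),
               "vitamin_a": (0, 800), "vitamin_b12": (0, 0),
               "vitamin_b6": (0.1, 0.35), "vitamin_c": (5, 35),
               "zinc": (0.2, 0.7)},
    "added_fats": {"energy_kcal": (860, 900), "fat": (95, 100),
               "calcium": (0, 2), "folate": (0, 1), "iron": (0, 0.2),
               "niacin": (0, 0.1), "protein": (0, 0.3),
               "riboflavin": (0, 0.05), "thiamin": (0, 0.02),
               "vitamin_a": (0, 900), "vitamin_b12": (0, 0),
               "vitamin_b6": (0, 0.02), "vitamin_c": (0, 0),
               "zinc": (0, 0.1)},
    "added_sugars": {"energy_kcal": (370, 400), "fat": (0, 0.2),
               "calcium": (0, 10), "folate": (0, 1), "iron": (0, 1),
               "niacin": (0, 0.2), "protein": (0, 0.3),
               "riboflavin": (0, 0.02), "thiamin": (0, 0.02),
               "vitamin_a": (0, 0), "vitamin_b12": (0, 0),
               "vitamin_b6": (0, 0.02), "vitamin_c": (0, 2),
               "zinc": (0, 0.2)},
    "beverages": {"energy_kcal": (25, 60), "fat": (0, 0.3),
               "calcium": (0, 15), "folate": (0, 5), "iron": (0, 0.5),
               "niacin": (0, 0.3), "protein": (0, 0.5),
               "riboflavin": (0, 0.05), "thiamin": (0, 0.03),
               "vitamin_a": (0, 20), "vitamin_b12": (0, 0),
               "vitamin_b6": (0, 0.05), "vitamin_c": (0, 30),
               "zinc": (0, 0.2)},
    "miscellaneous": {"energy_kcal": (0, 5), "fat": (0, 0.1),
               "calcium": (0, 5), "folate": (0, 1), "iron": (0, 0.2),
               "niacin": (0, 0.1), "protein": (0, 0.2),
               "riboflavin": (0, 0.01), "thiamin": (0, 0.01),
               "vitamin_a": (0, 2), "vitamin_b12": (0, 0),
               "vitamin_b6": (0, 0.01), "vitamin_c": (0, 2),
               "zinc": (0, 0.1)},
}

# typical adult-scale daily gram portion medians per group (lo, hi)
_PORTION_MEDIANS: dict[str, tuple[float, float]] = {
    "grains": (150, 350), "legumes_nuts_seeds": (40, 150),
    "dairy": (100, 300), "meat_fish_eggs": (30, 120),
    "vegetables": (40, 120), "fruits": (50, 150),
    "starchy_roots": (100, 250), "added_fats": (10, 30),
    "added_sugars": (10, 40), "beverages": (100, 300),
    "miscellaneous": (50, 300),
}

# human-milk composition per 100 g (energy density 0.66 kcal/g)
_BREASTMILK_ROW = {
    "energy_kcal": 66.0, "fat": 3.8, "calcium": 28.0, "folate": 8.5,
    "iron": 0.03, "niacin": 0.17, "protein": 1.0, "riboflavin": 0.035,
    "thiamin": 0.021, "vitamin_a": 60.0, "vitamin_b12": 0.05,
    "vitamin_b6": 0.011, "vitamin_c": 4.0, "zinc": 0.12,
}

# roster templates (sex, age_months); "child" is the guaranteed index child
# whose age is drawn uniformly in 12-23 months.  Sizes 2-8 exercise every
# AME branch (exclusively breastfed infants, 6-11-month siblings, older
# children, multiple adults).
_ROSTER_TEMPLATES: tuple[tuple[tuple[str, int | str], ...], ...] = (
    (("female", 288), ("child", "child")),
    (("male", 312), ("female", 288), ("child", "child")),
    (("male", 340), ("female", 300), ("child", "child"), ("male", 60)),
    (("male", 320), ("female", 290), ("child", "child"), ("female", 9)),
    (("male", 360), ("female", 330), ("child", "child"), ("male", 4),
     ("female", 84)),
    (("male", 420), ("female", 390), ("female", 216), ("child", "child"),
     ("male", 120), ("female", 48)),
    (("male", 460), ("female", 430), ("male", 240), ("female", 220),
     ("child", "child"), ("male", 150), ("female", 100), ("male", 36)),
)


@dataclass
class EnvironmentSpec:
    """Knobs fixing the shape of a generated food environment."""

    n_foods: int = 40
    rare_fraction: float = 0.25
    rare_propensity: tuple[float, float] = (0.004, 0.025)
    common_propensity: tuple[float, float] = (0.10, 0.90)
    seasonal_fraction: float = 0.0
    season_length_months: int = 4
    n_nonnutritive: int = 2
    n_child_inappropriate: int = 1
    portion_sigma: tuple[float, float] = (0.3, 0.6)
    #: child propensity = household propensity times this factor
    child_propensity_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_foods < 5:
            raise ValidationError(
                "environments need at least 5 foods to be meaningful"
            )
        for lo, hi in (self.rare_propensity, self.common_propensity):
            if not (0 <= lo <= hi <= 1):
                raise ValidationError("propensity ranges must lie in [0, 1]")


@dataclass
class DivergenceKnobs:
    """Controllable divergence between the paired survey arms."""

    questionnaire_coverage: float = 1.0
    hces_window_months: tuple[int, ...] = tuple(range(1, 13))
    recall_window_months: tuple[int, ...] = tuple(range(1, 13))
    recall_days: int = 7
    propensity_noise_sd: float = 0.0
    n_households: int = 300
    n_children: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.questionnaire_coverage <= 1:
            raise ValidationError("questionnaire coverage must be in (0, 1]")
        if not self.hces_window_months or not self.recall_window_months:
            raise ValidationError("survey windows must be non-empty")
        if self.recall_days not in (7, 14):
            raise ValidationError("recall_days must be 7 or 14")
        if self.propensity_noise_sd < 0:
            raise ValidationError("propensity noise must be non-negative")


@dataclass
class Environment:
    """A generated food environment: per-food truth plus lookup tables."""

    foods: pd.DataFrame          # one row per food with all truth columns
    taxonomy: FoodTaxonomy
    fct: FoodCompositionTable
    availability: pd.DataFrame   # foods x 12 months, boolean
    spec: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    seed: int = 0

    @property
    def food_ids(self) -> list[str]:
        return self.foods["food_id"].tolist()


def generate_environment(spec: EnvironmentSpec | None = None,
                         seed: int = 0) -> Environment:
    """Draw a reproducible food environment; same seed, same environment."""
    spec = spec or EnvironmentSpec()
    rng = np.random.default_rng([seed, 101])
    n = spec.n_foods
    food_ids = [f"food_{i:03d}" for i in range(n)]

    slots = [_TEMPLATE[i % len(_TEMPLATE)] for i in range(n)]
    rng.shuffle(slots)
    groups = [g for g, _ in slots]
    subgroups = [sg for _, sg in slots]
    is_nutritive = np.ones(n, dtype=bool)
    child_ok = np.ones(n, dtype=bool)
    # dedicate the last few foods to the special subgroups
    special = 0
    for k in range(spec.n_nonnutritive):
        i = n - 1 - special
        groups[i], subgroups[i] = _NONNUTRITIVE_SUBGROUP
        is_nutritive[i] = False
        special += 1
    for k in range(spec.n_child_inappropriate):
        i = n - 1 - special
        groups[i], subgroups[i] = _INAPPROPRIATE_SUBGROUP
        child_ok[i] = False
        special += 1

    n_rare = int(round(spec.rare_fraction * n))
    rare = np.zeros(n, dtype=bool)
    rare[rng.choice(n, size=n_rare, replace=False)] = True
    p_house = np.where(
        rare,
        rng.uniform(*spec.rare_propensity, size=n),
        rng.uniform(*spec.common_propensity, size=n),
    )
    p_child = np.clip(p_house * spec.child_propensity_factor, 0, 1)
    p_child[~child_ok] = 0.0  # young children never consume these

    avail = np.ones((n, 12), dtype=bool)
    n_seasonal = int(round(spec.seasonal_fraction * n))
    seasonal_idx = rng.choice(n, size=n_seasonal, replace=False)
    for i in seasonal_idx:
        start = int(rng.integers(0, 12))
        avail[i, :] = False
        for m in range(spec.season_length_months):
            avail[i, (start + m) % 12] = True

    portion_median = np.array([
        rng.uniform(*_PORTION_MEDIANS[g]) for g in groups
    ])
    portion_sigma = rng.uniform(*spec.portion_sigma, size=n)

    comp_rows = []
    for g in groups:
        ranges = _COMPOSITION_RANGES[g]
        comp_rows.append({key: rng.uniform(lo, hi)
                          for key, (lo, hi) in ranges.items()})
    comp = pd.DataFrame(comp_rows)
    comp.insert(0, "food_id", food_ids)
    comp = pd.concat(
        [comp, pd.DataFrame([{"food_id": BREASTMILK, **_BREASTMILK_ROW}])],
        ignore_index=True,
    )

    foods = pd.DataFrame({
        "food_id": food_ids,
        "food_name": [f"Food {i}" for i in range(n)],
        "subgroup_id": subgroups,
        "group_id": groups,
        "is_nutritive": is_nutritive,
        "child_appropriate": child_ok,
        "p_household": p_house,
        "p_child": p_child,
        "portion_median_g": portion_median,
        "portion_sigma": portion_sigma,
    })
    taxonomy = FoodTaxonomy(foods[list(FoodTaxonomy.COLUMNS)].copy())
    fct = FoodCompositionTable(comp)
    availability = pd.DataFrame(avail, index=food_ids,
                                columns=list(range(1, 13)))
    return Environment(foods=foods, taxonomy=taxonomy, fct=fct,
                       availability=availability, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------


def _portion_draws(rng: np.random.Generator, env: Environment,
                   shape: tuple[int, int]) -> np.ndarray:
    """Log-normal adult-scale daily-gram portions, truncated at 3 sigma."""
    mu = np.log(env.foods["portion_median_g"].to_numpy())
    sigma = env.foods["portion_sigma"].to_numpy()
    draws = rng.lognormal(mean=mu, sigma=sigma, size=shape)
    return np.minimum(draws, np.exp(mu + 3 * sigma))


def _noisy(rng: np.random.Generator, p: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return p
    return np.clip(p + rng.normal(0.0, sd, size=p.shape), 0.0, 1.0)


def _build_roster(rng: np.random.Generator, n_units: int,
                  prefix: str) -> pd.DataFrame:
    """Draw household rosters from the templates; one index child each."""
    t_idx = rng.integers(0, len(_ROSTER_TEMPLATES), size=n_units)
    child_ages = rng.integers(12, 24, size=n_units)
    rows = []
    for h in range(n_units):
        hh_id = f"{prefix}{h:04d}"
        for j, (sex, age) in enumerate(_ROSTER_TEMPLATES[t_idx[h]]):
            if sex == "child":
                rows.append((hh_id, f"{hh_id}_c", int(child_ages[h]),
                             "female" if h % 2 else "male", False, "no"))
            else:
                lact = "unknown" if sex == "female" and age >= 180 else "no"
                rows.append((hh_id, f"{hh_id}_m{j}", int(age), sex, False,
                             lact))
    return pd.DataFrame(rows, columns=[
        "household_id", "person_id", "age_months", "sex", "pregnant",
        "lactating",
    ])


def generate_hces(env: Environment, knobs: DivergenceKnobs,
                  references: NutrientReference | None = None,
                  cfg: AnalysisConfig | None = None) -> SurveyDataset:
    """Generate a household survey arm from the environment truth.

    Foods outside the questionnaire coverage never appear in the records.
    The returned dataset carries a ``truth`` frame with the index child's
    true daily gram intakes, for redistribution-recovery tests.
    """
    references = references or NutrientReference()
    cfg = cfg or AnalysisConfig()
    n_foods = len(env.food_ids)
    cover_rng = np.random.default_rng([knobs.seed, 7])
    n_cov = max(1, int(round(knobs.questionnaire_coverage * n_foods)))
    covered = np.zeros(n_foods, dtype=bool)
    covered[cover_rng.choice(n_foods, size=n_cov, replace=False)] = True

    rng = np.random.default_rng([knobs.seed, 11])
    roster = _build_roster(rng, knobs.n_households, "hh")
    amet = ame._vector_ame(roster, references, cfg)
    totals = amet.groupby("household_id")["adjusted_ame"].sum()
    kids = amet[(amet["age_months"] >= 12) & (amet["age_months"] < 24)]
    kids = kids.sort_values(["household_id", "age_months", "person_id"])
    kids = kids.groupby("household_id", as_index=False).first()
    child_ame = kids.set_index("household_id")["adjusted_ame"]
    hh_ids = totals.index.to_numpy()
    nh = len(hh_ids)

    months = rng.choice(np.array(knobs.hces_window_months), size=nh)
    avail = env.availability.to_numpy()[:, months - 1].T  # nh x n_foods
    p = _noisy(rng, env.foods["p_household"].to_numpy(), knobs.propensity_noise_sd)
    consume = (rng.random((nh, n_foods)) < p[None, :]) & avail & covered[None, :]
    portions = _portion_draws(rng, env, (nh, n_foods))

    quantity = (portions * totals.to_numpy()[:, None] * knobs.recall_days)
    hh_idx, f_idx = np.nonzero(consume)
    records = pd.DataFrame({
        "household_id": hh_ids[hh_idx],
        "food_id": np.array(env.food_ids)[f_idx],
        "quantity_g": quantity[hh_idx, f_idx],
        "recall_days": knobs.recall_days,
    })
    truth_g_day = portions * child_ame.reindex(totals.index).to_numpy()[:, None]
    truth = pd.DataFrame({
        "household_id": hh_ids[hh_idx],
        "child_id": kids.set_index("household_id")["person_id"]
                        .reindex(totals.index).to_numpy()[hh_idx],
        "food_id": np.array(env.food_ids)[f_idx],
        "true_g_per_day": truth_g_day[hh_idx, f_idx],
    })
    questionnaire = frozenset(np.array(env.food_ids)[covered])
    return SurveyDataset(
        kind="hces", roster=roster, records=records, taxonomy=env.taxonomy,
        recall_days=knobs.recall_days,
        window_months=tuple(knobs.hces_window_months),
        questionnaire=questionnaire, truth=truth,
    )


def generate_recall(env: Environment, knobs: DivergenceKnobs,
                    references: NutrientReference | None = None,
                    cfg: AnalysisConfig | None = None) -> SurveyDataset:
    """Generate a 24HR arm: one-day child intakes from child propensities."""
    references = references or NutrientReference()
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng([knobs.seed, 13])
    n_foods = len(env.food_ids)
    nc = knobs.n_children
    ages = rng.integers(12, 24, size=nc)
    child_ids = np.array([f"ch{c:04d}" for c in range(nc)])
    roster = pd.DataFrame({
        "household_id": [f"chh{c:04d}" for c in range(nc)],
        "person_id": child_ids,
        "age_months": ages,
        "sex": np.where(np.arange(nc) % 2 == 0, "male", "female"),
        "pregnant": False,
        "lactating": "no",
    })
    eers = np.array([references.eer(int(a), "male") for a in ages])
    child_ame = (eers / references.adult_male_eer) * np.array(
        [1.0 - cfg.breastmilk_fraction(int(a)) for a in ages]
    )

    months = rng.choice(np.array(knobs.recall_window_months), size=nc)
    avail = env.availability.to_numpy()[:, months - 1].T
    p = _noisy(rng, env.foods["p_child"].to_numpy(), knobs.propensity_noise_sd)
    consume = (rng.random((nc, n_foods)) < p[None, :]) & avail
    portions = _portion_draws(rng, env, (nc, n_foods))
    grams = portions * child_ame[:, None]

    c_idx, f_idx = np.nonzero(consume)
    records = pd.DataFrame({
        "child_id": child_ids[c_idx],
        "household_id": roster["household_id"].to_numpy()[c_idx],
        "food_id": np.array(env.food_ids)[f_idx],
        "quantity_g": grams[c_idx, f_idx],
    })
    return SurveyDataset(
        kind="recall24h", roster=roster, records=records,
        taxonomy=env.taxonomy, recall_days=1,
        window_months=tuple(knobs.recall_window_months),
    )


def write_environment(env: Environment, path: str) -> None:
    """Write taxonomy.csv, fct.csv, and environment_truth.json."""
    os.makedirs(path, exist_ok=True)
    env.taxonomy.to_csv(os.path.join(path, "taxonomy.csv"))
    env.fct.to_csv(os.path.join(path, "fct.csv"))
    truth = {
        "seed": env.seed,
        "foods": env.foods.to_dict(orient="records"),
        "availability": {f: [int(v) for v in env.availability.loc[f]]
                         for f in env.availability.index},
    }
    with open(os.path.join(path, "environment_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
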