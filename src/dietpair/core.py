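"""Shared domain types, reference tables, delimited-text I/O, and validation.

The package models diets of 12-23-month-old children from two kinds of
consumption surveys: household consumption and expenditure surveys (HCES),
which record food quantities per household over a 7- or 14-day recall, and
individual quantitative 24-hour recalls (24HR), which record one-day intakes
per child.  Everything downstream (adult-male-equivalent redistribution,
linear-programming parameter generation, diet optimization, agreement
statistics) consumes the types defined here.

All delimited files are UTF-8, comma-separated, with a header row; grams are
decimal numbers.  Ages are stored in months everywhere and age bands are
half-open ``[lo, hi)`` intervals in months, which avoids year/month mixing at
the under-two boundary.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NUTRIENTS",
    "NUTRIENT_UNITS",
    "BREASTMILK",
    "Person",
    "Household",
    "ConsumptionRecord",
    "FoodTaxonomy",
    "FoodCompositionTable",
    "NutrientReference",
    "AnalysisConfig",
    "SurveyDataset",
    "ValidationReport",
    "SchemaError",
    "ValidationError",
    "ConfigurationError",
    "load_survey",
    "write_survey",
    "load_taxonomy",
    "load_fct",
    "load_references",
    "validate_pair",
]

#: The 13 modeled nutrients (energy is handled separately as the diet's
#: isocaloric constraint, not as a nutrient goal).
NUTRIENTS: tuple[str, ...] = (
    "fat",
    "calcium",
    "folate",
    "iron",
    "niacin",
    "protein",
    "riboflavin",
    "thiamin",
    "vitamin_a",
    "vitamin_b12",
    "vitamin_b6",
    "vitamin_c",
    "zinc",
)

NUTRIENT_UNITS: dict[str, str] = {
    "fat": "g",
    "protein": "g",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "niacin": "mg",
    "riboflavin": "mg",
    "thiamin": "mg",
    "vitamin_b6": "mg",
    "vitamin_c": "mg",
    "folate": "ug",
    "vitamin_a": "ug_re",
    "vitamin_b12": "ug",
}

#: Identifier used for breastmilk as a food, a subgroup, and a group.
BREASTMILK = "breastmilk"


class SchemaError(ValueError):
    """A delimited file is missing a mandatory column."""


class ValidationError(ValueError):
    """Row-level data problems; carries the offending row descriptions."""

    def __init__(self, message: str, rows: Sequence[str] = ()):
        super().__init__(message)
        self.rows = list(rows)


class ConfigurationError(ValueError):
    """A reference table or policy table cannot answer a required lookup."""


# ---------------------------------------------------------------------------
# people and households
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Person:
    """A household member, defined by age, sex, and physiological status.

    ``lactating`` is tri-valued: explicit "yes"/"no" from the survey, or
    "unknown" when the roster does not record it.  Unknown status is resolved
    by :func:`dietpair.ame.infer_lactation`, never implicitly.
    """

    person_id: str
    age_months: int
    sex: str  # "male" | "female"
    pregnant: bool = False
    lactating: str = "unknown"  # "yes" | "no" | "unknown"

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValidationError(f"person {self.person_id}: negative age")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"person {self.person_id}: sex {self.sex!r}")
        if self.pregnant and self.sex == "male":
            raise ValidationError(f"person {self.person_id}: pregnant male")
        if self.lactating not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"person {self.person_id}: lactating {self.lactating!r}"
            )


@dataclass(frozen=True)
class ConsumptionRecord:
    food_id: str
    quantity_g: float  # per recall period (HCES) or per day (24HR)

    def __post_init__(self) -> None:
        if self.quantity_g < 0:
            raise ValidationError(f"food {self.food_id}: negative quantity")


@dataclass
class Household:
    household_id: str
    members: list[Person]
    recall_days: int = 7
    records: list[ConsumptionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.recall_days not in (7, 14):
            raise ValidationError(
                f"household {self.household_id}: recall_days must be 7 or 14"
            )
        if not self.members:
            raise ValidationError(f"household {self.household_id}: no members")


# ---------------------------------------------------------------------------
# taxonomy and composition
# ---------------------------------------------------------------------------


class FoodTaxonomy:
    """food -> (name, subgroup, group, is_nutritive, child_appropriate).

    Every subgroup maps to exactly one group, and breastmilk is always present
    as a dedicated food, subgroup, and group.
    """

    COLUMNS = ("food_id", "food_name", "subgroup_id", "group_id",
               "is_nutritive", "child_appropriate")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise SchemaError(f"taxonomy missing columns: {sorted(missing)}")
        table = table.copy()
        for col in ("is_nutritive", "child_appropriate"):
            table[col] = table[col].astype(bool)
        dup = table["food_id"].duplicated()
        if dup.any():
            raise ValidationError(
                "duplicate food_ids in taxonomy",
                rows=table.loc[dup, "food_id"].tolist(),
            )
        sg2g = table.groupby("subgroup_id")["group_id"].nunique()
        bad = sg2g[sg2g > 1]
        if len(bad):
            raise ValidationError(
                f"subgroups map to multiple groups: {sorted(bad.index)}"
            )
        if BREASTMILK not in set(table["food_id"]):
            row = pd.DataFrame(
                [[BREASTMILK, "Breastmilk", BREASTMILK, BREASTMILK, True, True]],
                columns=self.COLUMNS,
            )
            table = pd.concat([table, row], ignore_index=True)
        self.table = table.set_index("food_id", drop=False)

    @property
    def food_ids(self) -> list[str]:
        return self.table["food_id"].tolist()

    def subgroup_of(self, food_id: str) -> str:
        return self.table.at[food_id, "subgroup_id"]

    def group_of_subgroup(self, subgroup_id: str) -> str:
        rows = self.table[self.table["subgroup_id"] == subgroup_id]
        return rows["group_id"].iloc[0]

    def group_of(self, food_id: str) -> str:
        return self.table.at[food_id, "group_id"]

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.table.index

    def unknown_foods(self, food_ids: Iterable[str]) -> list[str]:
        """Food ids in the records that the taxonomy cannot resolve."""
        return sorted(set(food_ids) - set(self.table.index))

    def to_csv(self, path: str) -> None:
        self.table.reset_index(drop=True).to_csv(path, index=False)


class FoodCompositionTable:
    """Energy (kcal) and the 13 modeled nutrients per 100 g edible portion."""

    def __init__(self, table: pd.DataFrame):
        required = {"food_id", "energy_kcal", *NUTRIENTS}
        missing = required - set(table.columns)
        if missing:
            raise SchemaError(f"fct missing columns: {sorted(missing)}")
        table = table.copy()
        num = table[["energy_kcal", *NUTRIENTS]]
        if (num.to_numpy(dtype=float) < 0).any():
            raise ValidationError("fct contains negative values")
        self.table = table.set_index("food_id", drop=False)

    def energy_per_100g(self, food_id: str) -> float:
        return float(self.table.at[food_id, "energy_kcal"])

    def row(self, food_id: str) -> pd.Series:
        return self.table.loc[food_id, ["energy_kcal", *NUTRIENTS]]

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.table.index

    def to_csv(self, path: str) -> None:
        self.table.reset_index(drop=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# nutrient and energy references
# ---------------------------------------------------------------------------

# Shipped defaults are placeholders in the spirit of the FAO/WHO references
# for a 12-23-month-old with low iron and zinc bioavailability; every value is
# overridable through references.yaml.
_DEFAULT_RNI = {
    "fat": 30.0,        # g/day (~30% of energy)
    "protein": 10.9,    # g/day
    "calcium": 500.0,   # mg/day
    "iron": 11.6,       # mg/day at low bioavailability
    "zinc": 8.4,        # mg/day at low bioavailability
    "niacin": 6.0,      # mg/day
    "riboflavin": 0.5,  # mg/day
    "thiamin": 0.5,     # mg/day
    "vitamin_b6": 0.5,  # mg/day
    "vitamin_c": 30.0,  # mg/day
    "folate": 150.0,    # ug/day
    "vitamin_a": 400.0, # ug RE/day
    "vitamin_b12": 0.9, # ug/day
}

# (age_lo_months, age_hi_months, sex or "any") -> kcal/day
_DEFAULT_EER_BANDS = [
    (0, 6, "any", 550.0),
    (6, 9, "any", 615.0),
    (9, 12, "any", 686.0),
    (12, 24, "any", 894.0),
    (24, 60, "any", 1300.0),
    (60, 120, "any", 1700.0),
    (120, 216, "male", 2300.0),
    (120, 216, "female", 2000.0),
    (216, 360, "male", 2800.0),   # adult male 18-29.9 y: the AME reference
    (216, 360, "female", 2300.0),
    (360, 1800, "male", 2600.0),
    (360, 1800, "female", 2200.0),
]

_ADULT_MALE_BAND = (216, 360, "male")


@dataclass
class NutrientReference:
    """RNIs for the modeled age group, EER bands, and physiological increments.

    ``eer_bands`` rows are ``(age_lo, age_hi, sex, kcal_day)`` with half-open
    month intervals; ``sex`` may be "any".  Pregnancy and lactation increments
    are additive kcal/day entries, keeping FAO-style adjustments data-driven.
    """

    rni: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RNI))
    eer_bands: list[tuple[int, int, str, float]] = field(
        default_factory=lambda: list(_DEFAULT_EER_BANDS)
    )
    pregnancy_increment_kcal: float = 285.0
    lactation_increment_kcal: float = 505.0
    bioavailability: dict[str, str] = field(
        default_factory=lambda: {"iron": "low", "zinc": "low"}
    )

    def __post_init__(self) -> None:
        for nutrient, value in self.rni.items():
            if value <= 0:
                raise ConfigurationError(f"RNI for {nutrient} must be > 0")
        if not any(
            (lo, hi, sex) == _ADULT_MALE_BAND
            for lo, hi, sex, _ in self.eer_bands
        ):
            raise ConfigurationError(
                "EER table must contain the adult-male 18-29.9 y band"
            )

    def eer(self, age_months: int, sex: str, pregnant: bool = False,
            lactating: bool = False) -> float:
        """Daily energy requirement in kcal for the given person."""
        for lo, hi, band_sex, kcal in self.eer_bands:
            if lo <= age_months < hi and band_sex in ("any", sex):
                if pregnant:
                    kcal += self.pregnancy_increment_kcal
                if lactating:
                    kcal += self.lactation_increment_kcal
                return kcal
        raise ConfigurationError(
            f"no EER band for age {age_months} months, sex {sex}"
        )

    @property
    def adult_male_eer(self) -> float:
        for lo, hi, sex, kcal in self.eer_bands:
            if (lo, hi, sex) == _ADULT_MALE_BAND:
                return kcal
        raise ConfigurationError("adult-male reference band missing")

    def to_yaml(self, path: str) -> None:
        payload = {
            "rni": self.rni,
            "eer_bands": [list(b) for b in self.eer_bands],
            "pregnancy_increment_kcal": self.pregnancy_increment_kcal,
            "lactation_increment_kcal": self.lactation_increment_kcal,
            "bioavailability": self.bioavailability,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "NutrientReference":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            rni=dict(payload["rni"]),
            eer_bands=[tuple(b) for b in payload["eer_bands"]],
            pregnancy_increment_kcal=payload.get("pregnancy_increment_kcal", 285.0),
            lactation_increment_kcal=payload.get("lactation_increment_kcal", 505.0),
            bioavailability=dict(payload.get("bioavailability", {})),
        )


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

#: Food-level serving-limit policy: ordered (upper cut-point, min, max) tiers
#: over the consumer fraction; a fraction belongs to the first tier whose
#: cut-point strictly exceeds it, and the last tier is closed above.  This
#: default table is a placeholder policy (the published mapping is external to
#: the sources this package reimplements); it is configurable end to end.
DEFAULT_SERVING_LIMIT_POLICY: tuple[tuple[float, float, float], ...] = (
    (0.10, 0.0, 1.0),
    (0.25, 0.0, 3.0),
    (0.50, 0.0, 5.0),
    (0.75, 0.0, 7.0),
    (1.0 + 1e-12, 1.0, 14.0),
)


@dataclass
class AnalysisConfig:
    """Every threshold used anywhere in the pipeline, with shipped defaults.

    ``breastmilk_energy_fraction`` maps half-open age bands in months to the
    recommended share of energy from breastmilk: 67% at 6-8 months, 55% at
    9-11 months, 39% at 12-23 months.  The household-food AME multiplier for
    an under-two member is one minus this share (0 below 6 months, when the
    infant is exclusively breastfed).
    """

    food_list_threshold: float = 0.05
    percentile_low: int = 10
    percentile_high: int = 90
    percentile_goal: int = 50
    rni_adequacy_floor: float = 0.65
    problem_nutrient_ceiling: float = 1.00
    source_threshold: float = 0.05
    max_fbr_candidates: int = 8
    breastmilk_energy_fraction: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(6, 9): 0.67, (9, 12): 0.55, (12, 24): 0.39}
    )
    breastmilk_energy_density: float = 0.66  # kcal/g
    energy_tolerance: float = 0.01
    min_sample_24hr: int = 50
    min_questionnaire_foods: int = 100
    serving_limit_policy: tuple[tuple[float, float, float], ...] = (
        DEFAULT_SERVING_LIMIT_POLICY
    )
    #: HCES consumer-fraction denominator: households with a 12-23-month-old
    #: child; widen to under-five households for small samples if set.
    hces_denominator_under5: bool = False
    #: Treat non-consumers as zeros when taking percentile bounds.
    include_nonconsumers: bool = True
    #: Breastmilk-adjust all under-two members, not only the index child.
    adjust_all_under2: bool = True
    #: Nutrient universe for good-source counting (all 13 by default).
    source_count_nutrients: tuple[str, ...] = NUTRIENTS

    def __post_init__(self) -> None:
        for name in ("food_list_threshold", "rni_adequacy_floor",
                     "problem_nutrient_ceiling", "source_threshold",
                     "energy_tolerance"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        cuts = [c for c, _, _ in self.serving_limit_policy]
        if cuts != sorted(cuts) or len(set(cuts)) != len(cuts):
            raise ConfigurationError("serving-limit policy cut-points unordered")

    def breastmilk_fraction(self, age_months: int) -> float:
        """Recommended breastmilk energy share for an under-two age in months."""
        for (lo, hi), frac in self.breastmilk_energy_fraction.items():
            if lo <= age_months < hi:
                return frac
        raise ConfigurationError(
            f"no breastmilk energy fraction configured for {age_months} months"
        )


# ---------------------------------------------------------------------------
# survey datasets
# ---------------------------------------------------------------------------

ROSTER_COLUMNS = ("household_id", "person_id", "age_months", "sex",
                  "pregnant", "lactating")
HCES_COLUMNS = ("household_id", "food_id", "quantity_g", "recall_days")
RECALL_COLUMNS = ("child_id", "household_id", "food_id", "quantity_g")


@dataclass
class SurveyDataset:
    """A loaded consumption survey plus roster metadata.

    ``kind`` is "hces" (household-level quantities per recall period) or
    "recall24h" (child-level one-day intakes).  ``records`` and ``roster``
    are tidy frames with the documented columns; ``questionnaire`` is the
    closed food list of an HCES instrument when known (used by the inclusion
    criteria); ``window_months`` is the set of survey months (1-12).
    """

    kind: str
    roster: pd.DataFrame
    records: pd.DataFrame
    taxonomy: FoodTaxonomy | None = None
    recall_days: int = 7
    window_months: tuple[int, ...] = tuple(range(1, 13))
    questionnaire: frozenset[str] | None = None
    truth: pd.DataFrame | None = None  # synthetic ground truth, if generated

    def __post_init__(self) -> None:
        if self.kind not in ("hces", "recall24h"):
            raise ValidationError(f"unknown survey kind {self.kind!r}")
        cols = HCES_COLUMNS if self.kind == "hces" else RECALL_COLUMNS
        missing = set(cols) - set(self.records.columns) - {"recall_days"}
        if missing:
            raise SchemaError(f"records missing columns: {sorted(missing)}")
        missing = set(ROSTER_COLUMNS) - set(self.roster.columns)
        if missing:
            raise SchemaError(f"roster missing columns: {sorted(missing)}")

    # -- derived views -----------------------------------------------------
    @property
    def n_households(self) -> int:
        return self.roster["household_id"].nunique()

    @property
    def n_children(self) -> int:
        """Children aged 12-23 months in the roster."""
        ages = self.roster["age_months"]
        return int(((ages >= 12) & (ages < 24)).sum())

    def eligible_households(self, under5: bool = False) -> pd.Index:
        """Households containing a 12-23-month-old (or under-five) child."""
        ages = self.roster["age_months"]
        mask = (ages < 60) if under5 else ((ages >= 12) & (ages < 24))
        return pd.Index(sorted(self.roster.loc[mask, "household_id"].unique()))

    def index_children(self) -> pd.DataFrame:
        """One 12-23-month-old child per household (youngest such child)."""
        kids = self.roster[
            (self.roster["age_months"] >= 12) & (self.roster["age_months"] < 24)
        ]
        kids = kids.sort_values(["household_id", "age_months", "person_id"])
        return kids.groupby("household_id", as_index=False).first()

    def households(self) -> list[Household]:
        """Materialize typed Household objects (HCES kind only)."""
        out = []
        rec_by_hh = dict(tuple(self.records.groupby("household_id")))
        for hh_id, group in self.roster.groupby("household_id"):
            members = [
                Person(str(r.person_id), int(r.age_months), str(r.sex),
                       bool(r.pregnant), str(r.lactating))
                for r in group.itertuples()
            ]
            recs = []
            if hh_id in rec_by_hh:
                recs = [
                    ConsumptionRecord(str(r.food_id), float(r.quantity_g))
                    for r in rec_by_hh[hh_id].itertuples()
                ]
            out.append(Household(str(hh_id), members, self.recall_days, recs))
        return out


@dataclass
class ValidationReport:
    """Inclusion-criteria report; reporting only, never fatal."""

    criteria: list[dict] = field(default_factory=list)
    unknown_foods: list[str] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str) -> None:
        self.criteria.append({"criterion": name, "passed": bool(passed),
                              "detail": detail})

    @property
    def all_passed(self) -> bool:
        return all(c["passed"] for c in self.criteria)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.criteria)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def _read_csv(path: str | io.TextIOBase, columns: Sequence[str],
              label: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(columns) - set(frame.columns)
    if missing:
        raise SchemaError(f"{label} missing columns: {sorted(missing)}")
    return frame


def _check_quantities(records: pd.DataFrame, label: str) -> None:
    bad = records[records["quantity_g"] < 0]
    if len(bad):
        rows = [
            f"row {i}: food {r.food_id} quantity {r.quantity_g}"
            for i, r in zip(bad.index, bad.itertuples())
        ]
        raise ValidationError(f"{label}: negative quantities", rows=rows)


def load_taxonomy(path: str) -> FoodTaxonomy:
    return FoodTaxonomy(_read_csv(path, FoodTaxonomy.COLUMNS, "taxonomy"))


def load_fct(path: str) -> FoodCompositionTable:
    return FoodCompositionTable(
        _read_csv(path, ("food_id", "energy_kcal", *NUTRIENTS), "fct")
    )


def load_references(path: str) -> NutrientReference:
    return NutrientReference.from_yaml(path)


def load_survey(path: str, kind: str,
                taxonomy: FoodTaxonomy | None = None) -> SurveyDataset:
    """Load a survey from a directory of CSVs written by :func:`write_survey`.

    Expects ``roster.csv`` plus ``hces_consumption.csv`` or
    ``recall_consumption.csv`` depending on ``kind``, and optionally
    ``questionnaire.csv`` (one ``food_id`` column) and ``meta.yaml``.
    Unparseable rows raise :class:`ValidationError` naming them; they are
    never silently dropped.
    """
    roster = _read_csv(os.path.join(path, "roster.csv"), ROSTER_COLUMNS,
                       "roster")
    roster["lactating"] = roster["lactating"].fillna("unknown")
    if kind == "hces":
        records = _read_csv(os.path.join(path, "hces_consumption.csv"),
                            HCES_COLUMNS, "hces_consumption")
        recall_days = int(records["recall_days"].iloc[0]) if len(records) else 7
    elif kind == "recall24h":
        records = _read_csv(os.path.join(path, "recall_consumption.csv"),
                            RECALL_COLUMNS, "recall_consumption")
        recall_days = 1
    else:
        raise ValidationError(f"unknown survey kind {kind!r}")
    _check_quantities(records, kind)

    questionnaire = None
    qpath = os.path.join(path, "questionnaire.csv")
    if os.path.exists(qpath):
        questionnaire = frozenset(pd.read_csv(qpath)["food_id"].astype(str))
    window = tuple(range(1, 13))
    mpath = os.path.join(path, "meta.yaml")
    if os.path.exists(mpath):
        with open(mpath) as fh:
            meta = yaml.safe_load(fh) or {}
        window = tuple(meta.get("window_months", window))
        recall_days = int(meta.get("recall_days", recall_days))
    return SurveyDataset(kind=kind, roster=roster, records=records,
                         taxonomy=taxonomy, recall_days=recall_days,
                         window_months=window, questionnaire=questionnaire)


def write_survey(dataset: SurveyDataset, path: str) -> None:
    """Write a survey to a directory so that ``load_survey`` round-trips it."""
    os.makedirs(path, exist_ok=True)
    dataset.roster.to_csv(os.path.join(path, "roster.csv"), index=False)
    if dataset.kind == "hces":
        records = dataset.records.copy()
        if "recall_days" not in records.columns:
            records["recall_days"] = dataset.recall_days
        records.to_csv(os.path.join(path, "hces_consumption.csv"), index=False)
    else:
        dataset.records.to_csv(
            os.path.join(path, "recall_consumption.csv"), index=False
        )
    if dataset.questionnaire is not None:
        pd.DataFrame({"food_id": sorted(dataset.questionnaire)}).to_csv(
            os.path.join(path, "questionnaire.csv"), index=False
        )
    with open(os.path.join(path, "meta.yaml"), "w") as fh:
        yaml.safe_dump(
            {"kind": dataset.kind, "recall_days": dataset.recall_days,
             "window_months": list(dataset.window_months)},
            fh, sort_keys=False,
        )


# ---------------------------------------------------------------------------
# paired-dataset inclusion criteria
# ---------------------------------------------------------------------------


def validate_pair(hces: SurveyDataset, recall: SurveyDataset,
                  cfg: AnalysisConfig | None = None) -> ValidationReport:
    """Check the paired-survey inclusion criteria; report, never abort.

    Criteria: the 24HR sample holds at least ``min_sample_24hr`` (default 50)
    children aged 12-23 months, and the HCES questionnaire lists at least
    ``min_questionnaire_foods`` (default 100) distinct foods.  Taxonomy
    closure failures (record foods the taxonomy cannot resolve) are reported
    alongside.
    """
    cfg = cfg or AnalysisConfig()
    report = ValidationReport()
    n = recall.n_children
    report.add(
        "recall_sample_size", n >= cfg.min_sample_24hr,
        f"{n} children aged 12-23 months (minimum {cfg.min_sample_24hr})",
    )
    if hces.questionnaire is not None:
        n_foods = len(hces.questionnaire)
    else:
        n_foods = hces.records["food_id"].nunique()
    report.add(
        "questionnaire_foods", n_foods >= cfg.min_questionnaire_foods,
        f"{n_foods} foods on the HCES instrument "
        f"(minimum {cfg.min_questionnaire_foods})",
    )
    for ds, label in ((hces, "hces"), (recall, "recall24h")):
        if ds.taxonomy is not None:
            unknown = ds.taxonomy.unknown_foods(ds.records["food_id"])
            if unknown:
                report.unknown_foods.extend(f"{label}:{f}" for f in unknown)
            report.add(f"taxonomy_closure_{label}", not unknown,
                       f"{len(unknown)} unresolved foods")
    return report
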