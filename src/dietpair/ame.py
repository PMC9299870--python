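"""Adult-male-equivalent (AME) redistribution of household food to a child.

An AME expresses a household member's energy requirement as a fraction of the
requirement of an adult male aged 18-29.9 years.  Household food quantities
are apportioned to members in proportion to their AMEs; for children under
two the AME is first scaled down by the share of energy that breastmilk is
recommended to supply (67% at 6-8 months, 55% at 9-11 months, 39% at 12-23
months), so a 12-23-month-old keeps 61% of the unadjusted requirement, and an
infant under six months — assumed exclusively breastfed — keeps none.

The index child's estimated intake of food f in grams/day is then

    g_day(f) = quantity_g(f) * q_child / recall_days,

where ``q_child`` is the child's adjusted AME divided by the household's
total adjusted AME.  The per-member analogue conserves mass exactly: summing
it over members recovers ``quantity_g / recall_days`` for every food.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    ConfigurationError,
    Household,
    NutrientReference,
    Person,
    SurveyDataset,
    ValidationError,
)

__all__ = [
    "AmeProfile",
    "infer_lactation",
    "compute_ame",
    "ame_profile",
    "redistribute",
    "redistribute_dataset",
    "breastmilk_portion",
]


@dataclass
class AmeProfile:
    """Per-member AMEs and quotients for one household.

    ``members`` has columns person_id, age_months, raw_ame,
    breastmilk_multiplier, adjusted_ame, quotient.  Quotients sum to one.
    """

    household_id: str
    members: pd.DataFrame
    total_ame: float

    def quotient(self, person_id: str) -> float:
        row = self.members[self.members["person_id"] == person_id]
        if row.empty:
            raise KeyError(person_id)
        return float(row["quotient"].iloc[0])


# ---------------------------------------------------------------------------
# lactation inference
# ---------------------------------------------------------------------------


def infer_lactation(household: Household) -> Household:
    """Resolve unknown lactation statuses from household composition.

    A non-pregnant woman of unknown status is assumed to be breastfeeding if
    an under-24-month child lives in the household.  Explicitly recorded
    statuses are never overridden — the assumption fills missing data only.
    """
    has_under2 = any(m.age_months < 24 for m in household.members)
    resolved = []
    for m in household.members:
        if (m.lactating == "unknown" and m.sex == "female"
                and not m.pregnant and m.age_months >= 120):
            status = "yes" if has_under2 else "no"
            m = Person(m.person_id, m.age_months, m.sex, m.pregnant, status)
        elif m.lactating == "unknown":
            m = Person(m.person_id, m.age_months, m.sex, m.pregnant, "no")
        resolved.append(m)
    return Household(household.household_id, resolved,
                     household.recall_days, household.records)


# ---------------------------------------------------------------------------
# AME computation
# ---------------------------------------------------------------------------


def _breastmilk_multiplier(age_months: int, cfg: AnalysisConfig) -> float:
    """Household-food share kept by a member after the breastmilk adjustment."""
    if age_months < 6:
        return 0.0  # exclusively breastfed: consumes no household food
    if age_months < 24:
        return 1.0 - cfg.breastmilk_fraction(age_months)
    return 1.0


def compute_ame(person: Person, references: NutrientReference,
                cfg: AnalysisConfig) -> tuple[float, float, float]:
    """Return (raw_ame, breastmilk_multiplier, adjusted_ame) for one person.

    raw_ame = EER(person) / EER(adult male 18-29.9 y); the multiplier applies
    the under-two breastmilk adjustment (1.0 from 24 months up).
    """
    lact = person.lactating == "yes"
    raw = references.eer(person.age_months, person.sex, person.pregnant,
                         lact) / references.adult_male_eer
    mult = _breastmilk_multiplier(person.age_months, cfg)
    return raw, mult, raw * mult


def ame_profile(household: Household, references: NutrientReference,
                cfg: AnalysisConfig) -> AmeProfile:
    """Compute per-member AMEs and quotients after lactation inference."""
    household = infer_lactation(household)
    rows = []
    for m in household.members:
        raw, mult, adj = compute_ame(m, references, cfg)
        if not cfg.adjust_all_under2 and m.age_months < 24:
            # config switch: adjust only 12-23-month-olds, leave younger
            # siblings unadjusted (interpretation exposed, default off)
            if not 12 <= m.age_months < 24:
                mult, adj = 1.0, raw
        rows.append((m.person_id, m.age_months, raw, mult, adj))
    members = pd.DataFrame(
        rows, columns=["person_id", "age_months", "raw_ame",
                       "breastmilk_multiplier", "adjusted_ame"],
    )
    total = float(members["adjusted_ame"].sum())
    if total <= 0:
        raise ValidationError(
            f"household {household.household_id}: total AME is zero"
        )
    members["quotient"] = members["adjusted_ame"] / total
    return AmeProfile(household.household_id, members, total)


# ---------------------------------------------------------------------------
# redistribution
# ---------------------------------------------------------------------------


def redistribute(household: Household, index_child: str,
                 references: NutrientReference,
                 cfg: AnalysisConfig | None = None) -> pd.Series:
    """Estimate the index child's daily gram intakes from household records.

    Returns a Series indexed by food_id:
    ``grams/day = quantity_g * q_child / recall_days``.
    """
    cfg = cfg or AnalysisConfig()
    profile = ame_profile(household, references, cfg)
    q = profile.quotient(index_child)
    grams = {}
    for rec in household.records:
        grams[rec.food_id] = (
            grams.get(rec.food_id, 0.0)
            + rec.quantity_g * q / household.recall_days
        )
    return pd.Series(grams, dtype=float, name=index_child)


def _vector_ame(roster: pd.DataFrame, references: NutrientReference,
                cfg: AnalysisConfig) -> pd.DataFrame:
    """Vectorized per-member adjusted AMEs for a whole roster frame.

    Applies the same lactation inference as :func:`infer_lactation`:
    unknown-status non-pregnant adult women lactate iff the household has an
    under-24-month member.
    """
    r = roster.copy()
    under2 = (
        r.assign(u2=r["age_months"] < 24).groupby("household_id")["u2"].any()
    )
    unknown = r["lactating"].isna() | (r["lactating"] == "unknown")
    inferred_yes = (
        unknown & (r["sex"] == "female") & (~r["pregnant"].astype(bool))
        & (r["age_months"] >= 120) & r["household_id"].map(under2)
    )
    lact = (r["lactating"] == "yes") | inferred_yes

    eer = np.empty(len(r), dtype=float)
    eer[:] = np.nan
    ages = r["age_months"].to_numpy()
    sexes = r["sex"].to_numpy()
    for lo, hi, band_sex, kcal in references.eer_bands:
        mask = (ages >= lo) & (ages < hi)
        if band_sex != "any":
            mask &= sexes == band_sex
        eer[mask & np.isnan(eer)] = kcal
    if np.isnan(eer).any():
        bad = r.loc[np.isnan(eer), ["person_id", "age_months", "sex"]]
        raise ConfigurationError(f"no EER band for members:\n{bad}")
    eer = eer + r["pregnant"].astype(bool).to_numpy() * references.pregnancy_increment_kcal
    eer = eer + lact.to_numpy() * references.lactation_increment_kcal

    raw = eer / references.adult_male_eer
    mult = np.ones(len(r))
    mult[ages < 24] = [
        _breastmilk_multiplier(int(a), cfg) for a in ages[ages < 24]
    ]
    if not cfg.adjust_all_under2:
        keep = (ages < 24) & ~((ages >= 12) & (ages < 24))
        mult[keep] = 1.0
    r["raw_ame"] = raw
    r["breastmilk_multiplier"] = mult
    r["adjusted_ame"] = raw * mult
    return r


def redistribute_dataset(dataset: SurveyDataset,
                         references: NutrientReference,
                         cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """AME-redistribute a whole HCES dataset to its index children.

    Returns a tidy frame (household_id, child_id, food_id, g_per_day) with
    one row per (household, food) record, covering every household that
    contains a 12-23-month-old child.  The youngest such child per household
    is the index child.
    """
    cfg = cfg or AnalysisConfig()
    if dataset.kind != "hces":
        raise ValidationError("redistribution applies to HCES datasets")
    roster = _vector_ame(dataset.roster, references, cfg)
    totals = roster.groupby("household_id")["adjusted_ame"].sum()
    if (totals <= 0).any():
        bad = sorted(totals[totals <= 0].index)
        raise ValidationError(f"households with zero total AME: {bad}")
    index_children = dataset.index_children()
    child_rows = roster.merge(
        index_children[["household_id", "person_id"]],
        on=["household_id", "person_id"],
    )
    quotient = (
        child_rows.set_index("household_id")["adjusted_ame"] / totals
    ).dropna()
    child_of = child_rows.set_index("household_id")["person_id"]

    recs = dataset.records
    recs = recs[recs["household_id"].isin(quotient.index)].copy()
    recs["g_per_day"] = (
        recs["quantity_g"].to_numpy()
        * recs["household_id"].map(quotient).to_numpy()
        / dataset.recall_days
    )
    recs["child_id"] = recs["household_id"].map(child_of)
    out = (
        recs.groupby(["household_id", "child_id", "food_id"], as_index=False)
        ["g_per_day"].sum()
    )
    return out


# ---------------------------------------------------------------------------
# breastmilk portion
# ---------------------------------------------------------------------------


def breastmilk_portion(daily_energy_requirement_kcal: float, age_months: int,
                       cfg: AnalysisConfig | None = None) -> float:
    """Daily breastmilk grams supplying the recommended energy share.

    grams/day = requirement * band fraction / energy density (0.66 kcal/g).
    """
    cfg = cfg or AnalysisConfig()
    if daily_energy_requirement_kcal < 0:
        raise ValidationError("energy requirement must be non-negative")
    frac = cfg.breastmilk_fraction(age_months)
    return daily_energy_requirement_kcal * frac / cfg.breastmilk_energy_density
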