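"""Paired-method agreement statistics and regional summary tables.

Two percentage-agreement statistics compare an item classification between a
household-survey-derived (HCES) and a 24-hour-recall-derived (24HR) analysis:

* overall agreement — matched items divided by the items present in either
  analysis (or by a fixed universe such as the 13 modeled nutrients);
  an item absent from one side carries the negative status there.
* eligible agreement — matched items divided by the items present in both
  analyses, which conditions out differences in the food lists themselves.

Percentages are computed in full precision and rounded half-up to one
decimal for table output; integer rounding is applied only where summary
tables conventionally print integers.

The module also bundles, as package data, the regional classification tables
from a published four-country HCES/24HR comparison covering eight
geographical areas (Guatemala, Uganda, Bangladesh, Kenya).  They serve as
worked examples: recomputing the agreement statistics from those tables
reproduces the printed per-region and summary values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Hashable, Iterable, Mapping

import numpy as np
import pandas as pd

from .core import NUTRIENTS, ValidationError
from .params import nearest_rank

__all__ = [
    "ItemStatusList",
    "AgreementResult",
    "overall_agreement",
    "eligible_agreement",
    "portion_ratio_summary",
    "summarize_regions",
    "round_half_up",
    "REGIONS",
    "load_regional_problem_nutrients",
    "load_regional_nutrient_sources",
    "load_regional_parameter_agreement",
    "problem_nutrient_agreement_by_region",
    "nutrient_source_agreement_by_region",
]

REGIONS = (
    "western_highlands", "eastern_uganda", "western_uganda", "sylhet",
    "kitui", "isiolo", "marsabit", "vihiga",
)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (printed tables use 76.9 / 84.6 style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q,
                                                      rounding=ROUND_HALF_UP))


@dataclass
class ItemStatusList:
    """Item -> status association for one analysis arm.

    Items absent from the mapping are "not present" in that arm; in overall
    mode they carry the negative status.  ``negative`` is the status meaning
    "no"/absent (False for boolean statuses).
    """

    statuses: dict[Hashable, Hashable]
    provenance: str = ""  # "hces" | "recall24h"
    negative: Hashable = False

    @classmethod
    def from_presence(cls, items: Iterable[Hashable],
                      provenance: str = "") -> "ItemStatusList":
        return cls({i: True for i in items}, provenance)

    @property
    def present(self) -> set:
        return set(self.statuses)

    def status(self, item: Hashable) -> Hashable:
        return self.statuses.get(item, self.negative)


@dataclass
class AgreementResult:
    mode: str        # "overall" | "eligible"
    matched: int
    denominator: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.matched / self.denominator

    @property
    def rounded(self) -> float:
        return round_half_up(self.percentage, 1)


def overall_agreement(a: ItemStatusList, b: ItemStatusList,
                      universe: Iterable[Hashable] | None = None
                      ) -> AgreementResult:
    """Matched items over the union of present items (or a fixed universe)."""
    items = set(universe) if universe is not None else a.present | b.present
    if not items:
        raise ValidationError("overall agreement over an empty item set")
    matched = sum(1 for i in items if a.status(i) == b.status(i))
    return AgreementResult("overall", matched, len(items))


def eligible_agreement(a: ItemStatusList, b: ItemStatusList
                       ) -> AgreementResult:
    """Matched items over the items present in both analyses."""
    both = a.present & b.present
    if not both:
        raise ValidationError("no items present in both analyses")
    matched = sum(1 for i in both if a.statuses[i] == b.statuses[i])
    return AgreementResult("eligible", matched, len(both))


# ---------------------------------------------------------------------------
# portion ratios
# ---------------------------------------------------------------------------


@dataclass
class PortionRatioSummary:
    ratios: pd.Series         # per matched food, hces / recall
    median_ratio: float
    band: tuple[float, float]
    share_within_band: float  # fraction of ratios inside the band


def portion_ratio_summary(hces_max_weekly_g: Mapping[str, float],
                          recall_max_weekly_g: Mapping[str, float],
                          band: tuple[float, float] = (0.95, 1.05)
                          ) -> PortionRatioSummary:
    """Per-food maximum-weekly-gram ratios (HCES/24HR) over matched foods.

    The maximum weekly grams of a food are its maximum weekly servings times
    its daily portion.  The median is nearest-rank.
    """
    matched = sorted(set(hces_max_weekly_g) & set(recall_max_weekly_g))
    matched = [f for f in matched if recall_max_weekly_g[f] > 0]
    if not matched:
        raise ValidationError("no matched foods with positive portions")
    ratios = pd.Series(
        {f: hces_max_weekly_g[f] / recall_max_weekly_g[f] for f in matched}
    )
    median = nearest_rank(ratios, 50)
    within = float(((ratios >= band[0]) & (ratios <= band[1])).mean())
    return PortionRatioSummary(ratios, median, band, within)


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------


def summarize_regions(per_region: Mapping[str, Mapping[str, float]]
                      ) -> pd.DataFrame:
    """Cross-region arithmetic means per metric, reported at one-decimal and
    integer rounding (both half-up)."""
    if not per_region:
        raise ValidationError("no regions to summarize")
    frame = pd.DataFrame(per_region).T  # regions x metrics
    means = frame.mean(axis=0)
    out = frame.T
    out["mean"] = means
    out["mean_1dp"] = [round_half_up(v, 1) for v in means]
    out["mean_int"] = [int(round_half_up(v, 0)) for v in means]
    return out


# ---------------------------------------------------------------------------
# bundled regional tables (worked examples)
# ---------------------------------------------------------------------------


def _data_csv(name: str) -> pd.DataFrame:
    with resources.files("dietpair.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_regional_problem_nutrients() -> pd.DataFrame:
    """13 x 16 indicator matrix: nutrient problem status per region and arm.

    Columns are ``<region>_recall24h`` / ``<region>_hces`` with 1 marking a
    problem nutrient.
    """
    return _data_csv("regional_problem_nutrients.csv").set_index("nutrient")


def load_regional_nutrient_sources() -> pd.DataFrame:
    """33 food subgroups x 16 columns of good-source nutrient counts.

    A "." marks a subgroup absent from that arm's food list; integers count
    the nutrients for which the subgroup was a good source (0 = present but
    a source of none).
    """
    return _data_csv("regional_nutrient_sources.csv").set_index("subgroup")


def load_regional_parameter_agreement() -> pd.DataFrame:
    """Input-parameter summary rows (counts, portion ratios, agreements)."""
    return _data_csv("regional_parameter_agreement.csv").set_index("metric")


def problem_nutrient_agreement_by_region() -> pd.Series:
    """Recompute per-region overall problem-nutrient agreement from the
    bundled indicator matrix over the fixed 13-nutrient universe."""
    table = load_regional_problem_nutrients()
    out = {}
    for region in REGIONS:
        a = ItemStatusList(
            {n: bool(v) for n, v in table[f"{region}_recall24h"].items()},
            "recall24h",
        )
        b = ItemStatusList(
            {n: bool(v) for n, v in table[f"{region}_hces"].items()}, "hces"
        )
        out[region] = overall_agreement(a, b, universe=NUTRIENTS).rounded
    return pd.Series(out, name="overall_agreement_pct")


def nutrient_source_agreement_by_region() -> pd.DataFrame:
    """Recompute eligible and overall good-source agreement per region.

    Status is the boolean "good source of at least one modeled nutrient";
    in overall mode a subgroup absent from one arm carries the negative
    status, so an absent-versus-source-of-none pair counts as a match.
    """
    table = load_regional_nutrient_sources()
    rows = {}
    for region in REGIONS:
        arms = {}
        for arm in ("recall24h", "hces"):
            col = table[f"{region}_{arm}"]
            present = col[col != "."]
            arms[arm] = ItemStatusList(
                {sg: int(v) >= 1 for sg, v in present.items()}, arm
            )
        overall = overall_agreement(arms["recall24h"], arms["hces"])
        eligible = eligible_agreement(arms["recall24h"], arms["hces"])
        rows[region] = {
            "eligible_pct": eligible.rounded,
            "overall_pct": overall.rounded,
            "n_eligible": eligible.denominator,
            "n_overall": overall.denominator,
        }
    return pd.DataFrame(rows).T
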