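"""Food lists, nearest-rank portions, serving tables, percentile bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietpair as dp
from dietpair.params import _consumer_fractions


def intake_frame(rows):
    return pd.DataFrame(rows, columns=["child_id", "food_id", "g_per_day"])


def recall_dataset(intakes: pd.DataFrame, n_children: int) -> dp.SurveyDataset:
    roster = pd.DataFrame({
        "household_id": [f"h{i}" for i in range(n_children)],
        "person_id": [f"c{i}" for i in range(n_children)],
        "age_months": 15, "sex": "male", "pregnant": False,
        "lactating": "no",
    })
    records = intakes.rename(columns={"g_per_day": "quantity_g"}).assign(
        household_id=lambda d: d["child_id"].str.replace("c", "h"))
    return dp.SurveyDataset("recall24h", roster, records, recall_days=1)


class TestFoodList:
    def _build(self, taxonomy, consumers_per_food, denominator):
        rows = [(f"c{i}", food, 100.0)
                for food, k in consumers_per_food.items()
                for i in range(k)]
        ds = recall_dataset(intake_frame(rows), denominator)
        return dp.build_food_list(ds, taxonomy, intakes=intake_frame(rows),
                                  denominator=denominator)

    def test_threshold_boundary_exactly_5pct_included(self, toy_taxonomy):
        got = self._build(toy_taxonomy, {"maize": 2}, 40)  # 5.0%
        assert "maize" in got

    def test_threshold_boundary_49pct_excluded(self, toy_taxonomy):
        got = self._build(toy_taxonomy, {"maize": 49, "beans": 500}, 1000)
        assert "maize" not in got and "beans" in got

    def test_non_nutritive_excluded_despite_high_consumption(
            self, toy_taxonomy):
        got = self._build(toy_taxonomy, {"water": 36, "milk": 20}, 40)
        assert "water" not in got and "milk" in got

    def test_breastmilk_always_included(self, toy_taxonomy):
        got = self._build(toy_taxonomy, {"maize": 20}, 40)
        assert dp.BREASTMILK in got

    def test_child_inappropriate_dropped_from_hces_only(self, toy_taxonomy,
                                                        references, cfg):
        rows = [(f"c{i}", "beer", 30.0) for i in range(20)]
        intakes = intake_frame(rows)
        recall = recall_dataset(intakes, 40)
        hces_list = dp.build_food_list(
            dp.SurveyDataset("hces", recall.roster,
                             recall.records.assign(recall_days=7),
                             recall_days=7),
            toy_taxonomy, cfg, references, intakes, 40)
        recall_list = dp.build_food_list(recall, toy_taxonomy, cfg,
                                         references, intakes, 40)
        assert "beer" not in hces_list
        assert "beer" in recall_list


class TestPortions:
    def test_median_over_consumers(self):
        intakes = intake_frame([("c1", "maize", 50.0), ("c2", "maize", 100.0),
                                ("c3", "maize", 150.0),
                                ("c4", "maize", 0.0)])
        assert dp.median_portion(intakes, "maize") == 100.0

    def test_single_consumer(self):
        intakes = intake_frame([("c1", "maize", 80.0)])
        assert dp.median_portion(intakes, "maize") == 80.0

    def test_even_count_takes_lower_nearest_rank(self):
        intakes = intake_frame([("c1", "maize", 50.0), ("c2", "maize", 100.0)])
        assert dp.median_portion(intakes, "maize") == 50.0

    def test_no_consumers_is_error(self):
        with pytest.raises(dp.core.ValidationError):
            dp.median_portion(intake_frame([]), "maize")


class TestServings:
    def test_weekly_grams_over_portion(self):
        intakes = intake_frame([("c1", "maize", 100.0)])
        servings = dp.servings_per_week(
            intakes, pd.Series({"maize": 100.0}), pd.Index(["c1"]))
        assert servings.at["c1", "maize"] == pytest.approx(7.0)

    def test_recall_day_scales_to_week(self):
        intakes = intake_frame([("c1", "maize", 50.0)])
        servings = dp.servings_per_week(
            intakes, pd.Series({"maize": 100.0}), pd.Index(["c1"]))
        assert servings.at["c1", "maize"] == pytest.approx(3.5)

    def test_non_consumer_gets_zero(self):
        intakes = intake_frame([("c1", "maize", 50.0)])
        servings = dp.servings_per_week(
            intakes, pd.Series({"maize": 100.0}), pd.Index(["c1", "c2"]))
        assert servings.at["c2", "maize"] == 0.0

    def test_zero_portion_is_configuration_error(self):
        with pytest.raises(dp.core.ConfigurationError):
            dp.servings_per_week(intake_frame([("c1", "maize", 50.0)]),
                                 pd.Series({"maize": 0.0}),
                                 pd.Index(["c1"]))


class TestAggregateBounds:
    def test_worked_percentiles(self, toy_taxonomy):
        values = [0, 0, 1, 2, 3, 7, 7, 14, 14, 21]
        servings = pd.DataFrame(
            {"maize": values}, index=[f"c{i}" for i in range(10)])
        sg, g, goals = dp.aggregate_bounds(servings, toy_taxonomy)
        assert sg["whole_grains"] == (0.0, 14.0)
        assert g["grains"] == (0.0, 14.0)
        assert goals["grains"] == 3.0

    def test_all_zero_subgroup(self, toy_taxonomy):
        servings = pd.DataFrame({"maize": [0.0] * 5},
                                index=[f"c{i}" for i in range(5)])
        sg, _, _ = dp.aggregate_bounds(servings, toy_taxonomy)
        assert sg["whole_grains"] == (0.0, 0.0)

    def test_single_child(self, toy_taxonomy):
        servings = pd.DataFrame({"maize": [4.0]}, index=["c1"])
        sg, g, goals = dp.aggregate_bounds(servings, toy_taxonomy)
        assert sg["whole_grains"] == (4.0, 4.0)
        assert goals["grains"] == 4.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 30), min_size=1, max_size=40))
    def test_percentile_monotonicity(self, values):
        p10 = dp.nearest_rank(values, 10)
        p50 = dp.nearest_rank(values, 50)
        p90 = dp.nearest_rank(values, 90)
        assert p10 <= p50 <= p90


class TestServingLimits:
    @pytest.mark.parametrize("fraction,expected", [
        (0.05, (0.0, 1.0)),
        (0.099, (0.0, 1.0)),
        (0.10, (0.0, 3.0)),
        (0.30, (0.0, 5.0)),
        (0.60, (0.0, 7.0)),
        (0.75, (1.0, 14.0)),   # boundary belongs to the upper tier
        (1.0, (1.0, 14.0)),
    ])
    def test_default_policy_tiers(self, fraction, expected):
        assert dp.food_serving_limits(fraction) == expected

    def test_unordered_policy_rejected(self):
        with pytest.raises(dp.core.ConfigurationError):
            dp.food_serving_limits(0.5, policy=((0.8, 0, 7), (0.2, 0, 1)))


class TestGenerateParameters:
    def test_breastmilk_fixed_at_seven_servings(self, default_pair,
                                                default_env, references, cfg):
        hces, recall = default_pair
        for ds in (hces, recall):
            p = dp.generate_parameters(ds, default_env.taxonomy, references,
                                       cfg)
            bm = p.food(dp.BREASTMILK)
            assert bm.min_servings_week == bm.max_servings_week == 7.0
            assert p.subgroup_bounds[dp.BREASTMILK] == (7.0, 7.0)
            # 894 kcal/day target, 39% from breastmilk at 0.66 kcal/g
            assert bm.portion_g_per_day == pytest.approx(894 * 0.39 / 0.66)

    def test_every_food_has_bounds_at_all_levels(self, default_pair,
                                                 default_env, references,
                                                 cfg):
        hces, _ = default_pair
        p = dp.generate_parameters(hces, default_env.taxonomy, references,
                                   cfg)
        for f in p.foods:
            sg = p.subgroup_of[f.food_id]
            assert sg in p.subgroup_bounds
            assert p.group_of_subgroup[sg] in p.group_bounds
        for sg, (lo, hi) in p.subgroup_bounds.items():
            assert lo <= hi
        for g in p.group_goals:
            lo, hi = p.group_bounds[g]
            assert lo <= p.group_goals[g] <= hi

    def test_json_round_trip(self, tmp_path, default_pair, default_env,
                             references, cfg):
        hces, _ = default_pair
        p = dp.generate_parameters(hces, default_env.taxonomy, references,
                                   cfg)
        path = tmp_path / "params.json"
        p.to_json(str(path))
        back = dp.ModelParameters.from_json(str(path))
        assert back.food_ids == p.food_ids
        assert back.subgroup_bounds == p.subgroup_bounds
        assert back.energy_target_kcal_day == p.energy_target_kcal_day

    def test_consumer_fraction_denominators_differ_by_kind(
            self, default_pair, references, cfg):
        """HCES fractions are per eligible household, 24HR per child."""
        hces, recall = default_pair
        ih, dh = dp.params.child_intake_table(hces, references, cfg)
        ir, dr = dp.params.child_intake_table(recall, references, cfg)
        assert dh == hces.eligible_households().size
        assert dr == recall.n_children
        fh = _consumer_fractions(ih, dh)
        assert ((fh >= 0) & (fh <= 1)).all()
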