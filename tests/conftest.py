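"""Shared fixtures: a tiny hand-built survey pair and a default synthetic
region, all generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

import dietpair as dp


@pytest.fixture(scope="session")
def toy_taxonomy() -> dp.FoodTaxonomy:
    rows = [
        ("maize", "Maize flour", "whole_grains", "grains", True, True),
        ("rice", "White rice", "refined_grains", "grains", True, True),
        ("beans", "Dry beans", "beans_lentils_peas", "legumes", True, True),
        ("milk", "Cow milk", "milk", "dairy", True, True),
        ("kale", "Kale", "dark_green_leafy_vegetables", "vegetables", True,
         True),
        ("water", "Water", "condiments_tea_water", "miscellaneous", False,
         True),
        ("beer", "Beer", "alcoholic_drinks", "beverages", True, False),
    ]
    return dp.FoodTaxonomy(pd.DataFrame(rows, columns=list(
        dp.FoodTaxonomy.COLUMNS)))


@pytest.fixture(scope="session")
def toy_fct(toy_taxonomy) -> dp.FoodCompositionTable:
    base = {n: 0.0 for n in dp.NUTRIENTS}
    rows = []
    for food, energy, over in [
        ("maize", 360.0, {"iron": 2.0, "protein": 8.0, "zinc": 1.5,
                          "thiamin": 0.3, "niacin": 2.0, "folate": 25.0}),
        ("rice", 130.0, {"protein": 2.5, "iron": 0.5, "zinc": 0.6}),
        ("beans", 140.0, {"iron": 2.5, "protein": 8.5, "zinc": 1.1,
                          "folate": 130.0, "calcium": 50.0}),
        ("milk", 65.0, {"calcium": 120.0, "protein": 3.3, "riboflavin": 0.18,
                        "vitamin_b12": 0.45, "vitamin_a": 46.0, "fat": 3.7}),
        ("kale", 35.0, {"vitamin_a": 380.0, "vitamin_c": 41.0, "iron": 1.6,
                        "folate": 62.0, "calcium": 150.0}),
        ("water", 0.0, {}),
        ("beer", 43.0, {}),
        ("breastmilk", 66.0, {"fat": 3.8, "protein": 1.0, "calcium": 28.0,
                              "vitamin_a": 60.0, "vitamin_c": 4.0,
                              "vitamin_b12": 0.05, "folate": 8.5}),
    ]:
        rows.append({"food_id": food, "energy_kcal": energy, **base, **over})
    return dp.FoodCompositionTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def references() -> dp.NutrientReference:
    return dp.NutrientReference()


@pytest.fixture(scope="session")
def cfg() -> dp.AnalysisConfig:
    return dp.AnalysisConfig()


def make_household(hh_id="h1", recall_days=7, records=(),
                   members=None) -> dp.Household:
    if members is None:
        members = [
            dp.Person("dad", 300, "male"),
            dp.Person("mum", 276, "female", lactating="unknown"),
            dp.Person("kid", 15, "male"),
        ]
    recs = [dp.ConsumptionRecord(f, g) for f, g in records]
    return dp.Household(hh_id, members, recall_days, recs)


@pytest.fixture(scope="session")
def default_env() -> dp.Environment:
    return dp.generate_environment(dp.EnvironmentSpec(), seed=11)


@pytest.fixture(scope="session")
def default_pair(default_env, references, cfg):
    knobs = dp.DivergenceKnobs(n_households=300, n_children=300, seed=11)
    hces = dp.generate_hces(default_env, knobs, references, cfg)
    recall = dp.generate_recall(default_env, knobs, references, cfg)
    return hces, recall


@pytest.fixture(scope="session")
def default_models(default_env, default_pair, references, cfg):
    """within/free DietModels for the HCES arm of the default region."""
    hces, _ = default_pair
    p = dp.generate_parameters(hces, default_env.taxonomy, references, cfg)
    within = dp.DietModel(p, default_env.fct, references, cfg,
                          mode="within_pattern")
    free = dp.DietModel(p, default_env.fct, references, cfg,
                        mode="free_pattern")
    return within, free
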