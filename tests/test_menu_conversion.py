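"""Menu arithmetic: energy fractions and gram-to-concentration rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepfast import menu_conversion as conv
from hepfast import synthetic_menus as syn


# (menu id, macro, documented percent of daily energy)
DAILY_FRACTIONS = [
    (1, "fat", 78.1),
    (2, "carbohydrate", 47.6),
    (2, "fat", 31.5),
    (3, "carbohydrate", 20.4),
    (3, "fat", 61.3),
    (4, "carbohydrate", 39.7),
    (4, "fat", 42.5),
]


@pytest.mark.parametrize("menu_id,macro,expected", DAILY_FRACTIONS)
def test_daily_energy_fractions(menus, menu_id, macro, expected):
    """Atwater 4/9/4 reproduces every documented daily energy fraction."""
    menu = {m.identifier: m for m in menus}[menu_id]
    mass = (menu.total_carbohydrate_g if macro == "carbohydrate"
            else menu.total_fat_g)
    assert conv.energy_fraction(mass, macro, menu.total_energy_kcal) \
        == pytest.approx(expected, abs=1e-9)


def test_energy_fraction_validation():
    with pytest.raises(ValueError):
        conv.energy_fraction(10, "fiber", 2000)
    with pytest.raises(ValueError):
        conv.energy_fraction(10, "fat", 0)
    assert conv.energy_fraction(0, "fat", 2000) == 0.0


def test_glucose_rule_reproduces_scenario_grid(menus, scenario_grid):
    """carb_g / 1.80 matches all 16 reference G_B0 values to one decimal."""
    for menu in menus:
        for meal in menu.meals:
            expected = scenario_grid[(menu.identifier, meal.label)][0]
            got = conv.carbs_to_glucose_concentration(meal.carbohydrate_g)
            assert round(got + 1e-12, 1) == pytest.approx(expected)


def test_fat_rule_reproduces_scenario_grid(menus, scenario_grid):
    """The fitted factor reproduces all 16 T_LB0 within 0.1 mmol/L."""
    factor = syn.fitted_fat_factor()
    assert 3.58 <= factor <= 3.60
    for menu in menus:
        for meal in menu.meals:
            expected = scenario_grid[(menu.identifier, meal.label)][1]
            got = conv.fat_to_tag_concentration(meal.fat_g, factor)
            assert abs(got - expected) <= 0.1 + 1e-9


def test_leave_one_out_fat_prediction(menus, scenario_grid):
    """Each held-out meal's T_LB0 is predicted within 0.1 mmol/L."""
    for menu in menus:
        for meal in menu.meals:
            key = (menu.identifier, meal.label)
            factor = syn.fitted_fat_factor(exclude=key)
            pred = conv.fat_to_tag_concentration(meal.fat_g, factor)
            assert abs(pred - scenario_grid[key][1]) <= 0.1 + 1e-9


def test_fit_conversion_factor_oracle():
    """Origin-constrained least squares against frozen oracle values."""
    # exact synthetic pairs grams = 2 * concentration
    pairs = [(2.0 * c, c) for c in (1.0, 3.5, 10.0)]
    assert conv.fit_conversion_factor(pairs) == pytest.approx(2.0)
    # carbohydrate pairs recover the 1.80 g L/mmol constant
    grid = syn.fixture_scenarios()
    carb_pairs = [(meal.carbohydrate_g, grid[(m.identifier, meal.label)][0])
                  for m in syn.fixture_menus() for meal in m.meals]
    assert conv.fit_conversion_factor(carb_pairs) \
        == pytest.approx(1.80, abs=0.01)
    # fat pairs give the documented fitted constant
    fat_pairs = [(meal.fat_g, grid[(m.identifier, meal.label)][1])
                 for m in syn.fixture_menus() for meal in m.meals]
    assert conv.fit_conversion_factor(fat_pairs) \
        == pytest.approx(3.585, abs=0.01)


def test_fit_conversion_factor_errors():
    with pytest.raises(ValueError):
        conv.fit_conversion_factor([(1.0, 1.0)])
    with pytest.raises(ValueError):
        conv.fit_conversion_factor([(1.0, 0.0), (2.0, 0.0)])


@settings(max_examples=50, deadline=None)
@given(st.floats(0.01, 500.0), st.floats(1.5, 8.0))
def test_conversion_homogeneity(grams, factor):
    """Doubling grams doubles both derived concentrations."""
    assert conv.carbs_to_glucose_concentration(2 * grams) \
        == pytest.approx(2 * conv.carbs_to_glucose_concentration(grams))
    assert conv.fat_to_tag_concentration(2 * grams, factor) \
        == pytest.approx(2 * conv.fat_to_tag_concentration(grams, factor))


def test_energy_fraction_closure(menus):
    """carb% + fat% + protein% closes at 100% (protein is the residual)."""
    for menu in menus:
        total = (conv.energy_fraction(menu.total_carbohydrate_g,
                                      "carbohydrate",
                                      menu.total_energy_kcal)
                 + conv.energy_fraction(menu.total_fat_g, "fat",
                                        menu.total_energy_kcal)
                 + conv.energy_fraction(menu.total_protein_g, "protein",
                                        menu.total_energy_kcal))
        assert total == pytest.approx(100.0, abs=0.2)


def test_menu_csv_round_trip(menus, tmp_path):
    path = tmp_path / "menu1.csv"
    conv.write_menu_csv(menus[0], path)
    back = conv.read_menu_csv(path, identifier=1)
    for a, b in zip(menus[0].meals, back.meals):
        assert a.label == b.label
        assert a.carbohydrate_g == pytest.approx(b.carbohydrate_g)
        assert a.energy_kcal == pytest.approx(b.energy_kcal)


def test_scenario_validation():
    with pytest.raises(ValueError):
        conv.MealScenario(-1.0, 2.0)
    scen = conv.MealScenario(3.2, 9.1, source="menu 1 lunch")
    assert "9.1" in scen.to_json()
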