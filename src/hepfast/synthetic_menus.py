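"""Menu fixtures and a synthetic menu generator.

``fixture_menus`` returns the four documented one-day meal plans: a
ketogenic menu (carbohydrate ~5% of energy, fat ~78%), a general-population
menu (carbohydrate ~48%, fat ~31%) and two intermediate menus.  Protein
grams are not printed in the source tables and are derived as the Atwater
residual ``(kcal - 4*carb - 9*fat)/4`` so that macronutrient energy
fractions close at 100% by construction; saturated-fat grams are carried as
metadata only.

``generate_menu`` draws random menus with the same structure: four meals,
~2000 kcal/day, carbohydrate energy fraction spanning the ketogenic to
general-population range (5-60%) and fat 20-80%, so both dietary regimes
arise.  Generated menus are valid inputs to ``menu_conversion``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .menu_conversion import ATWATER, MEAL_LABELS, Meal, Menu

__all__ = ["MenuGeneratorConfig", "generate_menu", "fixture_menus",
           "fixture_meal_energy_shares", "fixture_scenarios",
           "fitted_fat_factor"]


# (menu id, sfa_g, ((label, carb_g, fat_g, kcal) x 4))
_FIXTURES = (
    (1, 37.0, (("breakfast", 2.7, 82.4, 859.2),
               ("lunch", 5.7, 32.6, 408.6),
               ("snack", 4.1, 19.5, 209.9),
               ("dinner", 12.6, 44.4, 584.0))),
    (2, 2.7, (("breakfast", 80.4, 5.9, 421.9),
              ("lunch", 89.7, 33.9, 904.7),
              ("snack", 29.3, 15.3, 284.1),
              ("dinner", 39.1, 15.1, 395.1))),
    (3, 27.1, (("breakfast", 13.9, 57.7, 612.9),
               ("lunch", 25.2, 27.7, 517.3),
               ("snack", 14.9, 32.4, 403.6),
               ("dinner", 47.9, 18.2, 461.8))),
    (4, 9.8, (("breakfast", 42.5, 16.7, 343.9),
              ("lunch", 77.8, 52.0, 971.2),
              ("snack", 24.3, 5.6, 164.4),
              ("dinner", 55.4, 20.8, 533.6))),
)


# Documented initial-concentration grid derived from the menus:
# (menu id, meal) -> (G_B0 mmol/L, T_LB0 mmol/L).  Used to calibrate the
# fat-to-TAG conversion factor and as the round-trip reference.
_SCENARIO_GRID: dict[tuple[int, str], tuple[float, float]] = {
    (1, "breakfast"): (1.5, 23.0), (1, "lunch"): (3.2, 9.1),
    (1, "snack"): (2.3, 5.4), (1, "dinner"): (7.0, 12.4),
    (2, "breakfast"): (44.7, 1.6), (2, "lunch"): (49.8, 9.5),
    (2, "snack"): (16.3, 4.3), (2, "dinner"): (21.7, 4.2),
    (3, "breakfast"): (7.7, 16.1), (3, "lunch"): (14.0, 7.7),
    (3, "snack"): (8.3, 9.0), (3, "dinner"): (26.6, 5.1),
    (4, "breakfast"): (23.6, 4.7), (4, "lunch"): (43.2, 14.5),
    (4, "snack"): (13.5, 1.6), (4, "dinner"): (30.8, 5.8),
}


def fixture_scenarios() -> dict[tuple[int, str], tuple[float, float]]:
    """Reference (G_B0, T_LB0) grid for the four fixture menus."""
    return dict(_SCENARIO_GRID)


def fitted_fat_factor(exclude: tuple[int, str] | None = None) -> float:
    """Fat-to-TAG conversion factor fitted on the fixture grid.

    Origin-constrained least squares of fat grams against the reference
    T_LB0 concentrations over the 16 (menu, meal) pairs; ``exclude`` drops
    one pair for leave-one-out prediction.
    """
    from .menu_conversion import fit_conversion_factor

    pairs = []
    for menu in fixture_menus():
        for meal in menu.meals:
            key = (menu.identifier, meal.label)
            if key == exclude:
                continue
            pairs.append((meal.fat_g, _SCENARIO_GRID[key][1]))
    return fit_conversion_factor(pairs)


def _residual_protein(carb_g: float, fat_g: float, kcal: float) -> float:
    return max(0.0, (kcal - ATWATER["carbohydrate"] * carb_g
                     - ATWATER["fat"] * fat_g) / ATWATER["protein"])


def fixture_menus() -> tuple[Menu, ...]:
    """The four documented menus, per-meal numbers verbatim."""
    menus = []
    for ident, sfa, meals in _FIXTURES:
        menus.append(Menu(
            ident,
            tuple(Meal(label, c, f, _residual_protein(c, f, e), e)
                  for label, c, f, e in meals),
            sfa_g=sfa,
        ))
    return tuple(menus)


def fixture_meal_energy_shares() -> dict[str, float]:
    """Mean energy share of each meal slot across the fixture menus."""
    menus = fixture_menus()
    shares = {}
    for label in MEAL_LABELS:
        shares[label] = float(np.mean(
            [m.meal(label).energy_kcal / m.total_energy_kcal
             for m in menus]))
    total = sum(shares.values())
    return {k: v / total for k, v in shares.items()}


@dataclass(frozen=True)
class MenuGeneratorConfig:
    """Study conditions for random menu generation.

    Defaults encode the menu-design constraints of the analysis: daily
    energy 2000 +/- 100 kcal, carbohydrate energy fraction from the
    ketogenic limit (5%) to the general-population upper guideline (60%),
    fat fraction 20-80%.  Protein takes the residual energy.  Meal-split
    weights default to the empirical energy shares of the fixture menus.
    """

    energy_kcal: float = 2000.0
    energy_tolerance_kcal: float = 100.0
    carb_fraction_range: tuple[float, float] = (0.05, 0.60)
    fat_fraction_range: tuple[float, float] = (0.20, 0.80)
    meal_weights: tuple[float, float, float, float] | None = None
    min_protein_fraction: float = 0.03
    seed: int | None = None

    def __post_init__(self):
        for lo, hi in (self.carb_fraction_range, self.fat_fraction_range):
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("fraction ranges must lie within (0, 1)")
        if (self.carb_fraction_range[0] + self.fat_fraction_range[0]
                + self.min_protein_fraction) >= 1.0:
            raise ValueError("infeasible fraction ranges: minimum "
                             "carbohydrate + fat + protein exceeds 100% "
                             "of energy")


def generate_menu(config: MenuGeneratorConfig | None = None,
                  rng: np.random.Generator | None = None,
                  identifier: str = "synthetic") -> Menu:
    """Draw one random menu under the configured study conditions."""
    config = config or MenuGeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    energy = float(rng.uniform(
        config.energy_kcal - config.energy_tolerance_kcal,
        config.energy_kcal + config.energy_tolerance_kcal))
    carb_frac = float(rng.uniform(*config.carb_fraction_range))
    fat_lo, fat_hi = config.fat_fraction_range
    fat_hi = min(fat_hi, 1.0 - config.min_protein_fraction - carb_frac)
    if fat_hi < fat_lo:
        raise ValueError("infeasible fraction ranges for drawn "
                         f"carbohydrate fraction {carb_frac:.3f}")
    fat_frac = float(rng.uniform(fat_lo, fat_hi))

    if config.meal_weights is None:
        weights = [fixture_meal_energy_shares()[lab] for lab in MEAL_LABELS]
    else:
        weights = list(config.meal_weights)
    if min(weights) < 0 or sum(weights) <= 0:
        raise ValueError("meal weights must be non-negative with a "
                         "positive sum")
    weights = np.array(weights, dtype=float) / sum(weights)

    meals = []
    for label, w in zip(MEAL_LABELS, weights):
        kcal = energy * float(w)
        carb_g = kcal * carb_frac / ATWATER["carbohydrate"]
        fat_g = kcal * fat_frac / ATWATER["fat"]
        protein_g = _residual_protein(carb_g, fat_g, kcal)
        meals.append(Meal(label, carb_g, fat_g, protein_g, kcal))
    return Menu(identifier, tuple(meals))
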