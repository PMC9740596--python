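"""Convert meal macronutrient masses into model initial conditions.

A menu is four meals, each with carbohydrate, fat and protein masses in
grams plus an energy content in kcal.  Two deterministic rules map a meal
onto the model's scenario-supplied plasma concentrations:

* carbohydrate grams -> initial plasma glucose ``G_B0``, dividing by
  0.180 g/mmol x 10 L (glucose molar mass over a 10 L distribution
  volume), i.e. ``G_B0 = carb_g / 1.80``;
* fat grams -> initial endogenous lipoprotein TAG ``T_LB0``, dividing by a
  single conversion factor fitted by origin-constrained least squares on
  the documented (fat g, T_LB0) pairs — no clean molar-mass/volume
  combination reproduces the printed grid, so the constant is estimated,
  not assumed.

Energy fractions use the Atwater factors 4/9/4 kcal per gram of
carbohydrate/fat/protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ATWATER",
    "GLUCOSE_G_PER_MMOL_L",
    "Meal",
    "Menu",
    "MealScenario",
    "energy_fraction",
    "carbs_to_glucose_concentration",
    "fat_to_tag_concentration",
    "fit_conversion_factor",
    "menu_to_scenarios",
    "read_menu_csv",
    "write_menu_csv",
]

#: kcal per gram of carbohydrate / fat / protein.
ATWATER: dict[str, float] = {"carbohydrate": 4.0, "fat": 9.0, "protein": 4.0}

#: Grams of glucose per (mmol/L of plasma): 0.180 g/mmol x 10 L.
GLUCOSE_G_PER_MMOL_L: float = 1.80

MEAL_LABELS = ("breakfast", "lunch", "snack", "dinner")


@dataclass(frozen=True)
class Meal:
    """One meal: macronutrient masses (g) and energy (kcal)."""

    label: str
    carbohydrate_g: float
    fat_g: float
    protein_g: float
    energy_kcal: float

    def __post_init__(self):
        for attr in ("carbohydrate_g", "fat_g", "protein_g"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if (self.carbohydrate_g or self.fat_g or self.protein_g) \
                and self.energy_kcal <= 0:
            raise ValueError("energy_kcal must be positive for a non-empty "
                             "meal")


@dataclass(frozen=True)
class Menu:
    """A one-day menu of four meals with optional metadata."""

    identifier: int | str
    meals: tuple[Meal, ...]
    sfa_g: float | None = None      # saturated fatty acids, metadata only

    def __post_init__(self):
        if len(self.meals) != 4:
            raise ValueError("a menu holds exactly four meals")

    @property
    def total_carbohydrate_g(self) -> float:
        return sum(m.carbohydrate_g for m in self.meals)

    @property
    def total_fat_g(self) -> float:
        return sum(m.fat_g for m in self.meals)

    @property
    def total_protein_g(self) -> float:
        return sum(m.protein_g for m in self.meals)

    @property
    def total_energy_kcal(self) -> float:
        return sum(m.energy_kcal for m in self.meals)

    def meal(self, label: str) -> Meal:
        for m in self.meals:
            if m.label == label:
                return m
        raise KeyError(f"no meal labelled {label!r}")


@dataclass(frozen=True)
class MealScenario:
    """Scenario-supplied initial plasma concentrations for one meal."""

    G_B0: float      # plasma glucose, mmol/L
    T_LB0: float     # plasma endogenous lipoprotein TAG, mmol/L
    source: str = ""

    def __post_init__(self):
        if self.G_B0 < 0 or self.T_LB0 < 0:
            raise ValueError("scenario concentrations must be non-negative")

    def to_json(self) -> str:
        return json.dumps({"G_B0": self.G_B0, "T_LB0": self.T_LB0,
                           "source": self.source})


def _round_half_up(x: float, decimals: int = 1) -> float:
    """Table-style display rounding (0.05 -> 0.1, not banker's)."""
    factor = 10.0 ** decimals
    return float(np.floor(x * factor + 0.5) / factor)


def energy_fraction(mass_g: float, macro: str, total_kcal: float) -> float:
    """Percent of daily energy supplied by ``mass_g`` of a macronutrient.

    Rounded to one decimal for reporting (half-up, matching the printed
    tables).
    """
    if macro not in ATWATER:
        raise ValueError(f"unknown macronutrient {macro!r}; expected one "
                         f"of {sorted(ATWATER)}")
    if total_kcal <= 0:
        raise ValueError("total_kcal must be positive")
    return _round_half_up(100.0 * mass_g * ATWATER[macro] / total_kcal)


def carbs_to_glucose_concentration(carbohydrate_g: float) -> float:
    """Initial plasma glucose (mmol/L) from carbohydrate mass (g)."""
    if carbohydrate_g < 0:
        raise ValueError("carbohydrate mass must be non-negative")
    return carbohydrate_g / GLUCOSE_G_PER_MMOL_L


def fat_to_tag_concentration(fat_g: float, factor: float) -> float:
    """Initial plasma endogenous TAG (mmol/L) from fat mass (g).

    ``factor`` is the grams-per-(mmol/L) conversion constant, normally
    obtained from :func:`fit_conversion_factor`.
    """
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if fat_g < 0:
        raise ValueError("fat mass must be non-negative")
    return fat_g / factor


def fit_conversion_factor(pairs: Iterable[tuple[float, float]]) -> float:
    """Origin-constrained least-squares slope of grams against mmol/L.

    Fits ``grams = factor * concentration`` over the given
    (grams, concentration) pairs and returns ``factor``.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    g = np.array([p[0] for p in pairs], dtype=float)
    c = np.array([p[1] for p in pairs], dtype=float)
    denom = float(np.dot(c, c))
    if denom == 0.0:
        raise ValueError("degenerate input: all concentrations are zero")
    return float(np.dot(c, g) / denom)


def menu_to_scenarios(menu: Menu, fat_factor: float,
                      decimals: int | None = 1) -> dict[str, MealScenario]:
    """Per-meal scenarios for a menu.

    With ``decimals=1`` (default) concentrations are rounded half-up to one
    decimal, matching the printed scenario grid; pass ``decimals=None`` for
    unrounded values.
    """
    scenarios = {}
    for meal in menu.meals:
        g = carbs_to_glucose_concentration(meal.carbohydrate_g)
        t = fat_to_tag_concentration(meal.fat_g, fat_factor)
        if decimals is not None:
            g = _round_half_up(g, decimals)
            t = _round_half_up(t, decimals)
        scenarios[meal.label] = MealScenario(
            g, t, source=f"menu {menu.identifier} {meal.label}")
    return scenarios


# --------------------------------------------------------------------------
# CSV schema: meal,carbohydrate_g,fat_g,protein_g,energy_kcal
# --------------------------------------------------------------------------

def write_menu_csv(menu: Menu, path) -> None:
    rows = [
        {"meal": m.label, "carbohydrate_g": m.carbohydrate_g,
         "fat_g": m.fat_g, "protein_g": m.protein_g,
         "energy_kcal": m.energy_kcal}
        for m in menu.meals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_menu_csv(path, identifier: int | str | None = None) -> Menu:
    df = pd.read_csv(path)
    required = {"meal", "carbohydrate_g", "fat_g", "protein_g",
                "energy_kcal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"menu CSV missing columns: {sorted(missing)}")
    meals = tuple(
        Meal(row["meal"], row["carbohydrate_g"], row["fat_g"],
             row["protein_g"], row["energy_kcal"])
        for _, row in df.iterrows()
    )
    if identifier is None:
        identifier = Path(path).stem
    return Menu(identifier, meals)
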