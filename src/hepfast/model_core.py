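"""Whole-body kinetic model of hepatic lipid metabolism.

The model couples four compartments — liver, skeletal muscle, adipose
tissue and blood plasma — through 23 balance equations for insulin,
glucose, glucose-6-phosphate, glycogen, pyruvate, free fatty acids (FFA),
triacylglycerol (TAG) pools and plasma lipoprotein species.  A meal enters
as a bolus of plasma glucose (``G_B``) and endogenous lipoprotein TAG
(``T_LB``); the balances then describe hepatic glycogen turnover, de novo
lipogenesis, VLDL secretion, chylomicron clearance and the insulin
modulation of each of these fluxes.

Three objects define the model surface:

``ParameterSet``
    the 81 named kinetic constants, 78 of which are varied in global
    sensitivity analysis (the three compartment volumes are held fixed);
``build_registry`` / ``REACTIONS``
    a registry of the 45 named reaction fluxes ``v1`` … ``v45`` from which
    every balance right-hand side is assembled — each flux knows the
    states it feeds with stoichiometric sign and factor;
``evaluate_rhs`` / ``make_rhs``
    the assembled derivative function (a hand-flattened fast path; the
    registry-assembled reference is ``registry_rhs`` and the two are held
    equal by the test suite).

Several printed constants are dimensionally inconsistent (e.g. the insulin
degradation constant ``k_d`` in L/mmol acting on insulin in pmol/L).  They
are implemented exactly as documented; ``units_report`` enumerates the
known mismatches rather than silently repairing them.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "STATE_UNITS",
    "STATE_COMPARTMENT",
    "DEFAULT_INITIAL",
    "PARAM_NAMES",
    "VARIED_ORDER",
    "Parameter",
    "ParameterSet",
    "default_parameters",
    "Reaction",
    "build_registry",
    "REACTIONS",
    "evaluate_rhs",
    "make_rhs",
    "registry_rhs",
    "reaction_rates",
    "initial_state",
    "units_report",
]

# --------------------------------------------------------------------------
# State vector
# --------------------------------------------------------------------------

#: Canonical state order (also the metabolite column order of the
#: sensitivity heat maps).  ``A_NB`` is the display name of the plasma
#: non-esterified fatty acid pool (``A_B`` in the balance notation).
STATE_NAMES: tuple[str, ...] = (
    "I",    # plasma insulin
    "G_L", "Y_L", "P_L", "R_L", "A_L", "S_L", "T_L",      # liver
    "G_M", "Y_M", "P_M", "R_M", "A_M", "T_M",             # muscle
    "P",                                                   # muscle AMP
    "T_A", "A_A", "L_A", "G_A",                            # adipose
    "T_CB", "A_NB", "T_LB", "G_B",                         # plasma
)

STATE_UNITS: dict[str, str] = {name: "mmol/L" for name in STATE_NAMES}
STATE_UNITS["I"] = "pmol/L"

STATE_COMPARTMENT: dict[str, str] = {
    "I": "plasma",
    **{s: "liver" for s in ("G_L", "Y_L", "P_L", "R_L", "A_L", "S_L", "T_L")},
    **{s: "muscle" for s in ("G_M", "Y_M", "P_M", "R_M", "A_M", "T_M", "P")},
    **{s: "adipose" for s in ("T_A", "A_A", "L_A", "G_A")},
    **{s: "plasma" for s in ("T_CB", "A_NB", "T_LB", "G_B")},
}

#: Default initial concentrations.  ``G_B`` and ``T_LB`` are scenario
#: supplied (they encode the meal) and are ``None`` here on purpose.
DEFAULT_INITIAL: dict[str, float | None] = {
    "I": 60.0,
    "G_L": 8.0, "Y_L": 50.0, "P_L": 2.06, "R_L": 0.37,
    "A_L": 0.57, "S_L": 0.0149, "T_L": 40.0,
    "G_M": 0.5, "Y_M": 20.0, "P_M": 0.133, "R_M": 0.009,
    "A_M": 0.53, "T_M": 14.8,
    "P": 0.0,
    "T_A": 500.0, "A_A": 0.57, "L_A": 0.17, "G_A": 2.53,
    "T_CB": 0.0, "A_NB": 0.5,
    "T_LB": None, "G_B": None,
}

State = namedtuple("State", STATE_NAMES)


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Parameter:
    """One named kinetic constant with unit and provenance note."""

    name: str
    value: float
    unit: str
    description: str
    note: str | None = None


# name, value, unit, description, provenance note (None = verbatim)
_PARAMETER_TABLE: tuple[tuple[str, float, str, str, str | None], ...] = (
    ("alpha_A", 15.60, "L", "adipose tissue volume", None),
    ("alpha_L", 1.60, "L", "liver tissue volume", None),
    ("alpha_M", 26.4, "L", "skeletal muscle volume", None),
    ("beta_G", 1.0, "-", "figure-row parameter with no recoverable printed "
     "value", "printed value not recoverable (lost table row); appears in "
     "no balance, so any positive nominal gives identical dynamics"),
    ("beta_6", 31.6, "L/min", "rate of liver de novo lipogenesis from "
     "pyruvate", None),
    ("beta_f", 0.117, "mmol/min", "adipose release of triacylglycerides to "
     "non-esterified fatty acids", None),
    ("beta_L", 12.0, "L/min", "liver glycogenolysis", None),
    ("beta_M", 82.5, "L/min", "muscle glycogenolysis", None),
    ("mu_amp", 1.8, "-", "basal adenosine monophosphate/diphosphate "
     "creation rate", None),
    ("mu_b", 0.133, "mmol/min", "lactate production by red blood cells",
     "enters the liver pyruvate balance twice as printed (net factor 2)"),
    ("mu_e", 0.420, "mmol/min", "muscle triglyceride breakdown to free "
     "fatty acids", "appears in no balance (the muscle TAG terms use "
     "m_e as printed); inert but varied"),
    ("mu_s", 7.19e6, "L mmol/min", "muscle free fatty acid esterification "
     "to triglycerides", "appears in no balance (the muscle TAG terms use "
     "m_s as printed); inert but varied"),
    ("mu_1", 0.588, "mmol/min", "plasma glucose usage", None),
    ("mu_3", 7.839e7, "L mmol/min", "muscle glucose-6-phosphate usage",
     None),
    ("mu_4", 100.0, "L/min", "muscle free fatty acid usage", None),
    ("c_0", 0.1, "mmol/L", "small smoothing parameter of the glycogen "
     "capacity switch", None),
    ("c_c", 2.5, "mmol/L", "range of glucose concentrations over which "
     "excess insulin secretion occurs", None),
    ("d_ba", 0.3, "mmol/min", "adipose uptake of glucose", None),
    ("k_10", 0.625, "mmol/L", "affinity for hydrolysis of triglycerides "
     "to secretory pool", None),
    ("k_11", 48.0, "mmol/min", "basal insulin secretion rate", None),
    ("k_12", 0.2, "-", "increased fraction of VLDL1 secretion by insulin",
     None),
    ("k_13", 15.0, "mmol/L", "rate at which insulin modifies the fraction "
     "of VLDL1 to VLDL2 secretion", None),
    ("k_14", 0.6, "-", "basal VLDL1 secretion fraction", None),
    ("k_22", 48.0, "mmol/min", "excess insulin secretion rate due to "
     "glucose stimulation", None),
    ("k_5", 8.23e7, "1/mmol", "flux control coefficient for insulin "
     "inhibition of free fatty acid oxidation", None),
    ("k_6", 0.3, "mmol/L", "affinity for VLDL2 triglyceride secretion "
     "through secretory pathway", None),
    ("k_61", 4.0, "L/min", "liver glucose dephosphorylation rate", None),
    ("k_6p", 6.56e8, "L^2/mmol min", "muscle glucose-6-phosphate to "
     "pyruvate conversion rate", None),
    ("k_7", 0.759, "L/min", "maximum rate of free fatty acid oxidation",
     None),
    ("k_8", 0.625, "mmol/L", "affinity for esterification of free fatty "
     "acids to triglycerides", None),
    ("k_9", 43.583, "mmol/L", "affinity of additional bulk lipidation",
     None),
    ("k_9a", 1.0, "L/min", "release of VLDL from secretory pathway", None),
    ("k_a", 0.1497, "L/min", "adipose FFA uptake of chylomicron "
     "triglycerides, insulin independent", None),
    ("k_aa", 3.11e5, "L^2/mmol min", "adipose FFA esterification to "
     "triglycerides", None),
    ("k_ai", 2.08e6, "1/mmol", "adipose FFA uptake of chylomicron "
     "triglycerides, insulin dependent", None),
    ("k_al", 2e-05, "L^2/mmol min", "pyruvate to acetyl coenzyme A "
     "conversion rate", None),
    ("k_ba", 0.0104, "L/min", "adipose uptake of endogenous lipoprotein "
     "triglycerides", None),
    ("k_bl", 0.156, "L/min", "liver uptake of plasma non-esterified fatty "
     "acids", None),
    ("k_bm", 0.226, "L/min", "muscle uptake of plasma non-esterified "
     "fatty acids", None),
    ("k_cl", 0.0075, "L/min", "liver FFA uptake of chylomicron "
     "triglycerides", None),
    ("k_cm", 0.0449, "L/min", "muscle FFA uptake of chylomicron "
     "triglycerides", None),
    ("k_d", 1.733e14, "L/mmol", "insulin degradation rate", None),
    ("k_dl", 3.5e8, "mmol/L", "liver glycogenolysis; insulin-inhibited "
     "rate", "printed '3.5 x 18^8'; corrected to 3.5 x 10^8"),
    ("k_dy", 4e8, "L/mmol", "muscle glycogenolysis; insulin-inhibited "
     "rate", None),
    ("k_ft", 1.67e14, "L/mmol", "adipose release of triglyceride to NEFA; "
     "insulin-inhibited rate", None),
    ("k_ga", 1.67e6, "-", "rate of glucose diffusion between plasma and "
     "adipose mediated by GLUT4", None),
    ("k_gi", 2.632e8, "mmol/L", "glucose diffusion between plasma and "
     "muscles, insulin-mediated", None),
    ("k_gl", 0.9277, "mmol/L", "plasma glucose diffusion rate to liver",
     None),
    ("k_gl2", 0.396, "mmol/L", "liver glucose diffusion rate to blood",
     None),
    ("k_gm", 0.0380, "mmol/L", "plasma glucose diffusion rate to muscle",
     None),
    ("k_gm2", 0.0380, "mmol/L", "muscle glucose diffusion rate to plasma",
     None),
    ("k_gp", 0.311, "L/min", "glucose-6-phosphate uptake from adipose "
     "glycerol", None),
    ("k_lp", 0.25, "-", "rate of plasma triglyceride uptake by adipose "
     "tissue", "appears in no balance; inert but varied"),
    ("k_LG", 8.95, "mmol/L", "Michaelis-Menten constant of glucokinase in "
     "liver", None),
    ("k_LH", 0.0115, "mmol/L", "Michaelis-Menten constant of hexokinase "
     "in liver", None),
    ("k_MH", 8.98, "mmol/L", "Michaelis-Menten constant of hexokinase in "
     "muscle", None),
    ("k_na", 0.0697, "L/min", "rate of plasma FFA uptake into adipose "
     "FFA", None),
    ("k_p", 1.41e7, "mmol/L", "rate of insulin-mediated "
     "glucose-6-phosphate to pyruvate", None),
    ("k_p6", 6.56e8, "L^2/mmol min", "constant of pyruvate conversion to "
     "glucose-6-phosphate", None),
    ("k_pp", 0.5, "-", "rate of muscle pyruvate transport to liver", None),
    ("k_r", 0.00058, "mmol", "rate of endogenously derived lipoprotein "
     "triglycerides taken up by liver as free fatty acids", None),
    ("k_rep", 2.98, "mmol/L", "glucose-6-phosphate inhibition constant of "
     "hexokinase", "figure-row alias k_re (mapping unconfirmed)"),
    ("k_t", 0.00348, "mmol/L", "uptake rate of plasma endogenous "
     "triglycerides into muscle free fatty acids", None),
    ("k_yl", 1.28e6, "-", "rate of glycogen synthesis stimulated by "
     "insulin", None),
    ("k_ym", 21.3641, "mmol/L", "glycogen synthesis rate (muscle)", None),
    ("l_max", 400.0, "mmol", "maximum glycogen store of liver", None),
    ("m_max", 100.0, "mmol", "maximum glycogen concentration (muscle)",
     None),
    ("v", 7.0, "mmol", "glucose threshold of insulin secretion",
     "figure-row alias v_min; Table description reads 'rate of glycogen "
     "transport' but the constant acts as the erf threshold"),
    ("v_10", 0.1, "mmol/min", "rate of triglyceride storage conversion to "
     "free fatty acids", None),
    ("v_12", 40.0, "mmol/L", "constant in triglyceride release into "
     "plasma", None),
    ("v_6", 0.0158, "mmol/L", "rate of liver FFA input to secretory pool",
     None),
    ("v_8", 0.333, "mmol/min", "rate of FFA input to storage pool", None),
    ("v_9", 0.0159, "mmol/L", "rate of triglyceride release into plasma",
     None),
    ("v_LG", 14.3, "mmol/min", "maximum rate of glucokinase in liver",
     None),
    ("v_LH", 5.57, "mmol/min", "maximum rate of hexokinase in liver",
     None),
    ("v_MH", 54.288, "mmol/min", "muscle hexokinase maximum rate", None),
    ("y_0", 0.1, "-", "range of glycogen concentration over which release "
     "drops to zero", None),
    ("alpha_G", 2.0, "mmol", "rate of glucose change in diet (exponential "
     "meal forcing time scale)", None),
    ("alpha_F", 2.0, "mmol/L", "rate of fat change in diet (exponential "
     "meal forcing time scale)", None),
    ("m_s", 0.8, "-", "insulin-dependent rate of skeletal muscle storage "
     "of FFA as triglycerides", None),
    ("m_e", 0.9, "-", "rate of skeletal muscle triglyceride breakdown to "
     "free fatty acids", None),
)

PARAM_NAMES: tuple[str, ...] = tuple(row[0] for row in _PARAMETER_TABLE)

#: The three compartment volumes are never varied in sensitivity analysis.
_FIXED_FOR_FAST = ("alpha_A", "alpha_L", "alpha_M")

#: Row order of the 78 varied parameters in the sensitivity heat maps.
VARIED_ORDER: tuple[str, ...] = (
    "beta_G", "beta_6", "beta_f", "beta_L", "beta_M",
    "mu_amp", "mu_e", "mu_s", "mu_1", "mu_b", "mu_3", "mu_4",
    "c_0", "c_c", "d_ba",
    "k_10", "k_11", "k_12", "k_13", "k_14", "k_22",
    "k_5", "k_6", "k_61", "k_6p", "k_7", "k_8", "k_9", "k_9a",
    "k_a", "k_aa", "k_ai", "k_al", "k_ba", "k_bl", "k_bm", "k_cl",
    "k_cm", "k_d", "k_dl", "k_dy", "k_ft", "k_ga", "k_gi", "k_gl",
    "k_gl2", "k_gm", "k_gm2", "k_gp", "k_lp", "k_LG", "k_LH", "k_MH",
    "k_na", "k_p", "k_p6", "k_pp", "k_r", "k_rep", "k_t", "k_yl", "k_ym",
    "l_max", "m_max", "v", "v_10", "v_12", "v_6", "v_8", "v_9",
    "v_LG", "v_LH", "v_MH", "y_0", "alpha_G", "alpha_F", "m_s", "m_e",
)

_ParamStruct = namedtuple("_ParamStruct", PARAM_NAMES)


class ParameterSet:
    """Immutable mapping of the 81 named kinetic constants.

    Values are plain floats; :meth:`struct` exposes them as a namedtuple for
    fast attribute access inside rate expressions.  ``replace`` returns a
    new set with selected values overridden (the config-override mechanism
    for alternative constants — the shipped defaults are never mutated).
    """

    def __init__(self, values: Mapping[str, float],
                 meta: Mapping[str, Parameter] | None = None):
        missing = set(PARAM_NAMES) - set(values)
        extra = set(values) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(
                f"parameter set mismatch: missing={sorted(missing)} "
                f"unknown={sorted(extra)}")
        self._values = {name: float(values[name]) for name in PARAM_NAMES}
        self._meta = dict(meta) if meta is not None else _DEFAULT_META
        self._struct: _ParamStruct | None = None

    # -- mapping surface ---------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self):
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return len(PARAM_NAMES)

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __eq__(self, other) -> bool:
        return (isinstance(other, ParameterSet)
                and self._values == other._values)

    def items(self):
        return self._values.items()

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    # -- views -------------------------------------------------------------
    def struct(self) -> _ParamStruct:
        if self._struct is None:
            self._struct = _ParamStruct(**self._values)
        return self._struct

    def meta(self, name: str) -> Parameter:
        return self._meta[name]

    def unit(self, name: str) -> str:
        return self._meta[name].unit

    @property
    def varied_names(self) -> tuple[str, ...]:
        return VARIED_ORDER

    def varied_for_fast(self, name: str) -> bool:
        return name not in _FIXED_FOR_FAST

    @property
    def varied_values(self) -> np.ndarray:
        return np.array([self._values[n] for n in VARIED_ORDER])

    def provenance_log(self) -> dict[str, str]:
        """Notes for every entry whose printed value needed interpretation."""
        return {p.name: p.note for p in self._meta.values()
                if p.note is not None}

    # -- modification ------------------------------------------------------
    def replace(self, **overrides: float) -> "ParameterSet":
        values = dict(self._values)
        for name, value in overrides.items():
            if name not in values:
                raise KeyError(f"unknown parameter {name!r}")
            values[name] = float(value)
        return ParameterSet(values, self._meta)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path=None) -> str | None:
        """Flat key/value dump with units and provenance, bit-exact floats."""
        doc = {
            name: {
                "value": float.hex(self._values[name]),
                "approx": self._values[name],
                "unit": self._meta[name].unit,
                "description": self._meta[name].description,
                **({"note": self._meta[name].note}
                   if self._meta[name].note else {}),
            }
            for name in PARAM_NAMES
        }
        text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source: str) -> "ParameterSet":
        """Accepts a YAML string or a path to a YAML file."""
        import os
        if os.path.exists(source):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        values = {}
        for name, entry in doc.items():
            raw = entry["value"] if isinstance(entry, dict) else entry
            values[name] = (float.fromhex(raw) if isinstance(raw, str)
                            else float(raw))
        return cls(values)


_DEFAULT_META: dict[str, Parameter] = {
    row[0]: Parameter(*row) for row in _PARAMETER_TABLE
}


def default_parameters() -> ParameterSet:
    """The 81 documented kinetic constants with corrections applied.

    The only value correction is the obvious mantissa/base typo in ``k_dl``
    (3.5 x 18^8 -> 3.5 x 10^8); every interpretation is recorded in
    :meth:`ParameterSet.provenance_log`.
    """
    return ParameterSet({row[0]: row[1] for row in _PARAMETER_TABLE})


# --------------------------------------------------------------------------
# Reaction registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One named model flux and where it enters the balances.

    ``stoich`` maps state name to the signed factor multiplying the rate in
    that state's *volume-scaled* balance (the alpha division is applied when
    the right-hand side is assembled).  TAG-to-FFA conversions carry the
    stoichiometric factor 3 (three fatty acids per triglyceride).
    """

    rid: str
    name: str
    rate: Callable
    stoich: Mapping[str, float]


def _F_I(st, p):
    """Insulin-modified VLDL secretion fraction."""
    return p.k_12 * math.tanh((p.v_12 - st.I) / p.k_13) + p.k_14


def _S_G(t, forcing):
    return 0.0 if forcing is None else forcing.S_G(t)


def _S_F(t, forcing):
    return 0.0 if forcing is None else forcing.S_F(t)


def build_registry(adipose_glucose_product: bool = False
                   ) -> tuple[Reaction, ...]:
    """Construct the 45-reaction registry.

    Indices named in the source analysis (v1, v2, v4, v5, v16–v19, v23–v25,
    v32–v34, v37–v40, v42–v45) are bound to their documented expressions;
    the remaining distinct balance terms receive the free indices in the
    order they appear reading down the balance table.  Reversible pairs
    (glycogen turnover in liver and muscle, muscle TAG storage/breakdown)
    are single net reactions, in the same style as the printed net
    transports v25 and v42.

    Parameters
    ----------
    adipose_glucose_product:
        Use the literally printed product form ``G_B*G_A`` for the
        plasma–adipose glucose exchange instead of the conservative
        difference form ``G_B - G_A`` (default).
    """
    if adipose_glucose_product:
        def v42_rate(st, p, t, f):
            return p.d_ba * (1.0 + p.k_ga * st.I) * st.G_B * st.G_A
    else:
        def v42_rate(st, p, t, f):
            return p.d_ba * (1.0 + p.k_ga * st.I) * (st.G_B - st.G_A)

    R = Reaction
    return (
        R("v1", "glucose-stimulated insulin production",
          lambda st, p, t, f: p.k_11 + p.k_22 * math.erf(
              (st.G_B - p.v) / p.c_c),
          {"I": +1}),
        R("v2", "insulin degradation",
          lambda st, p, t, f: p.k_d * st.I, {"I": -1}),
        R("v3", "glucose input from the diet",
          lambda st, p, t, f: _S_G(t, f), {"G_L": +1}),
        R("v4", "glucose flux to plasma from the liver",
          lambda st, p, t, f: p.k_gl * st.G_L, {"G_L": -1, "G_B": +1}),
        R("v5", "glucose flux from plasma to the liver",
          lambda st, p, t, f: p.k_gl2 * st.G_B, {"G_L": +1, "G_B": -1}),
        R("v6", "liver glucokinase phosphorylation",
          lambda st, p, t, f: p.v_LG * st.G_L / (p.k_LG + st.G_L),
          {"G_L": -1, "P_L": +1}),
        R("v7", "liver hexokinase phosphorylation (G6P-inhibited)",
          lambda st, p, t, f: p.v_LH * st.G_L / (p.k_LH + st.G_L)
          / (1.0 + p.k_rep * st.P_L),
          {"G_L": -1, "P_L": +1}),
        R("v8", "liver glucose-6-phosphate dephosphorylation",
          lambda st, p, t, f: p.k_61 * st.P_L, {"G_L": +1, "P_L": -1}),
        R("v9", "liver glycogen turnover (synthesis - glycogenolysis)",
          lambda st, p, t, f: 0.5 * p.k_yl * st.I * st.P_L
          * (1.0 + math.tanh((p.l_max - st.Y_L) / p.c_0))
          - p.beta_L / (1.0 + p.k_dl * st.I) * st.Y_L / (st.Y_L + p.y_0),
          {"Y_L": +1, "P_L": -1}),
        R("v10", "liver insulin-mediated glycolysis (G6P to pyruvate)",
          lambda st, p, t, f: p.k_p * st.I * st.P_L,
          {"P_L": -1, "R_L": +1}),
        R("v11", "glycerol to glucose-6-phosphate (adipose to liver)",
          lambda st, p, t, f: p.k_gp * st.L_A, {"P_L": +1, "L_A": -1}),
        R("v12", "liver de novo lipogenesis from pyruvate",
          lambda st, p, t, f: p.beta_6 * st.R_L / (1.0 + p.k_p6 * st.I),
          {"P_L": +1, "R_L": -1}),
        R("v13", "muscle pyruvate transport to liver",
          lambda st, p, t, f: p.k_pp * st.R_M, {"R_L": +1, "R_M": -1}),
        R("v14", "lactate production by red blood cells",
          lambda st, p, t, f: p.mu_b, {"R_L": +2}),
        R("v15", "liver pyruvate to acetyl-CoA",
          lambda st, p, t, f: p.k_al * st.I * st.R_L,
          {"R_L": -1, "A_L": +1}),
        R("v16", "uptake of exogenous plasma triglycerides into liver "
          "free fatty acids",
          lambda st, p, t, f: p.k_cl * st.T_CB, {"A_L": +3, "T_CB": -1}),
        R("v17", "free fatty acid transport from plasma to liver",
          lambda st, p, t, f: p.k_bl * st.A_NB, {"A_L": +1, "A_NB": -1}),
        R("v18", "free fatty acid synthesis from plasma endogenous "
          "triglycerides (liver uptake)",
          lambda st, p, t, f: p.k_r * st.T_LB, {"A_L": +3, "T_LB": -1}),
        R("v19", "triglyceride storage conversion to free fatty acids in "
          "the liver",
          lambda st, p, t, f: p.v_10 * st.T_L / (p.k_10 + st.T_L),
          {"A_L": +3, "T_L": -1}),
        R("v20", "liver FFA input to the TAG secretory pool",
          lambda st, p, t, f: p.v_6 * st.A_L / (p.k_6 + st.A_L),
          {"A_L": -3, "S_L": +1}),
        R("v21", "liver FFA esterification to the TAG storage pool",
          lambda st, p, t, f: p.v_8 * st.A_L / (p.k_8 + st.A_L),
          {"A_L": -3, "T_L": +1}),
        R("v22", "liver free fatty acid oxidation (insulin-inhibited)",
          lambda st, p, t, f: p.k_7 * st.A_L / (1.0 + p.k_5 * st.I),
          {"A_L": -1}),
        R("v23", "export of triglycerides from the secretory pool to "
          "plasma",
          lambda st, p, t, f: p.k_9a * st.S_L, {"S_L": -1, "T_LB": +1}),
        R("v24", "rate of triglyceride release into plasma (VLDL "
          "secretion)",
          lambda st, p, t, f: _F_I(st, p) * p.v_9 * st.T_L
          / (p.k_9 + st.T_L),
          {"T_L": -1, "T_LB": +1}),
        R("v25", "insulin-stimulated glucose transport between plasma and "
          "muscle",
          lambda st, p, t, f: (1.0 + p.k_gi * st.I)
          * (p.k_gm * st.G_B - p.k_gm2 * st.G_M),
          {"G_M": +1, "G_B": -1}),
        R("v26", "muscle hexokinase phosphorylation (G6P-inhibited)",
          lambda st, p, t, f: p.v_MH * st.G_M / (p.k_MH + st.G_M)
          / (1.0 + p.k_rep * st.P_M),
          {"G_M": -1, "P_M": +1}),
        R("v27", "muscle glycogen turnover (synthesis - glycogenolysis)",
          lambda st, p, t, f: 0.5 * p.k_ym * st.I * st.P_M
          * (1.0 + math.tanh((p.m_max - st.Y_M) / p.c_0))
          - p.beta_M / (1.0 + p.k_dy * st.I) * st.Y_M / (st.Y_M + p.y_0),
          {"Y_M": +1, "P_M": -1}),
        R("v28", "muscle glucose-6-phosphate to pyruvate",
          lambda st, p, t, f: p.k_6p * st.I * st.P_M,
          {"P_M": -1, "R_M": +1}),
        R("v29", "muscle pyruvate usage (AMP-coupled)",
          lambda st, p, t, f: p.mu_3 * st.R_M * st.I * st.P,
          {"R_M": -1, "P": -1}),
        R("v30", "muscle TAG turnover (storage - breakdown)",
          lambda st, p, t, f: p.m_s * st.I * st.A_M - p.m_e,
          {"A_M": -3, "T_M": +1}),
        R("v31", "muscle free fatty acid usage (AMP-coupled)",
          lambda st, p, t, f: p.mu_4 * st.A_M * st.P,
          {"A_M": -1, "P": -1}),
        R("v32", "uptake of exogenous plasma triglycerides into muscle "
          "free fatty acids",
          lambda st, p, t, f: p.k_cm * st.T_CB, {"A_M": +3, "T_CB": -1}),
        R("v33", "free fatty acid uptake from plasma into muscle",
          lambda st, p, t, f: p.k_bm * st.A_NB, {"A_M": +1, "A_NB": -1}),
        R("v34", "uptake of plasma endogenous triglycerides into muscle "
          "free fatty acids",
          lambda st, p, t, f: p.k_t * st.T_LB, {"A_M": +3, "T_LB": -1}),
        R("v35", "basal AMP creation",
          lambda st, p, t, f: p.mu_amp, {"P": +1}),
        R("v36", "adipose FFA esterification to triglycerides",
          lambda st, p, t, f: p.k_aa * st.I * st.A_A * st.G_A,
          {"T_A": +1, "A_A": -3, "G_A": -1}),
        R("v37", "release of adipose triglycerides to plasma free fatty "
          "acids (insulin-inhibited)",
          lambda st, p, t, f: p.beta_f / (1.0 + p.k_ft * st.I * st.I),
          {"T_A": -1, "L_A": +1, "A_NB": +3}),
        R("v38", "uptake of plasma exogenous triglycerides by adipose "
          "tissue",
          lambda st, p, t, f: p.k_a * (1.0 + p.k_ai * st.I) * st.T_CB,
          {"T_CB": -1}),
        R("v39", "uptake of plasma endogenous triglycerides into adipose "
          "free fatty acids",
          lambda st, p, t, f: p.k_ba * st.T_LB, {"A_A": +3, "T_LB": -1}),
        R("v40", "uptake of plasma free fatty acids into adipose free "
          "fatty acids",
          lambda st, p, t, f: p.k_na * st.A_NB, {"A_A": +1, "A_NB": -1}),
        R("v41", "plasma glucose usage",
          lambda st, p, t, f: p.mu_1, {"G_B": -1}),
        R("v42", "glucose transport between plasma and adipose tissue",
          v42_rate, {"G_A": +1, "G_B": -1}),
        R("v43", "fat input from the diet",
          lambda st, p, t, f: _S_F(t, f), {"T_CB": +1}),
        R("v44", "rate of complete uptake of plasma exogenous "
          "triglycerides by adipose tissue",
          lambda st, p, t, f: p.k_a * (1.0 + p.k_ai * st.I) * st.T_CB,
          {"A_A": +3}),
        R("v45", "adipose tissue uptake of exogenous triglycerides from "
          "plasma (to plasma FFA)",
          lambda st, p, t, f: p.k_a * (1.0 + p.k_ai * st.I) * st.T_CB,
          {"A_NB": +3}),
    )


#: Default registry (difference form of the plasma–adipose glucose
#: exchange).
REACTIONS: tuple[Reaction, ...] = build_registry()

REACTION_IDS: tuple[str, ...] = tuple(r.rid for r in REACTIONS)


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------

def _volume_factors(p, uniform_liver_volume: bool) -> dict[str, float]:
    aL = p.alpha_L
    aM = p.alpha_L if uniform_liver_volume else p.alpha_M
    aA = p.alpha_L if uniform_liver_volume else p.alpha_A
    factors = {}
    for name in STATE_NAMES:
        comp = STATE_COMPARTMENT[name]
        if name in ("I", "P") or comp == "plasma":
            factors[name] = 1.0  # printed without a volume factor
        elif comp == "liver":
            factors[name] = aL
        elif comp == "muscle":
            factors[name] = aM
        else:
            factors[name] = aA
    return factors


def make_rhs(params: ParameterSet, forcing=None,
             uniform_liver_volume: bool = False,
             adipose_glucose_product: bool = False) -> Callable:
    """Build a fast ``f(t, y) -> dy/dt`` closure for the 23 balances.

    The closure binds every constant as a local float; it is the integration
    path.  ``registry_rhs`` assembles the same right-hand side from the
    reaction registry and the two agree to floating precision (enforced by
    the test suite).
    """
    p = params.struct()
    erf, tanh = math.erf, math.tanh

    k_11, k_22, c_c, v_thr, k_d = p.k_11, p.k_22, p.c_c, p.v, p.k_d
    k_gl, k_gl2, v_LG, k_LG, v_LH, k_LH, k_rep, k_61 = (
        p.k_gl, p.k_gl2, p.v_LG, p.k_LG, p.v_LH, p.k_LH, p.k_rep, p.k_61)
    k_yl, l_max, c_0, beta_L, k_dl, y_0, k_p, k_gp, beta_6, k_p6 = (
        p.k_yl, p.l_max, p.c_0, p.beta_L, p.k_dl, p.y_0, p.k_p, p.k_gp,
        p.beta_6, p.k_p6)
    k_pp, mu_b, k_al = p.k_pp, p.mu_b, p.k_al
    k_cl, k_bl, k_r, v_6, k_6, v_10, k_10, v_8, k_8, k_7, k_5 = (
        p.k_cl, p.k_bl, p.k_r, p.v_6, p.k_6, p.v_10, p.k_10, p.v_8, p.k_8,
        p.k_7, p.k_5)
    k_9a, k_12, v_12, k_13, k_14, v_9, k_9 = (
        p.k_9a, p.k_12, p.v_12, p.k_13, p.k_14, p.v_9, p.k_9)
    k_gi, k_gm, k_gm2, v_MH, k_MH = p.k_gi, p.k_gm, p.k_gm2, p.v_MH, p.k_MH
    k_ym, m_max, beta_M, k_dy, k_6p, mu_3, mu_4, m_s, m_e, k_cm, k_bm, \
        k_t, mu_amp = (p.k_ym, p.m_max, p.beta_M, p.k_dy, p.k_6p, p.mu_3,
                       p.mu_4, p.m_s, p.m_e, p.k_cm, p.k_bm, p.k_t,
                       p.mu_amp)
    k_aa, beta_f, k_ft, k_a, k_ai, k_ba, k_na, d_ba, k_ga, mu_1 = (
        p.k_aa, p.beta_f, p.k_ft, p.k_a, p.k_ai, p.k_ba, p.k_na, p.d_ba,
        p.k_ga, p.mu_1)

    aL = p.alpha_L
    aM = aL if uniform_liver_volume else p.alpha_M
    aA = aL if uniform_liver_volume else p.alpha_A

    if forcing is None:
        def S_G(t):
            return 0.0

        def S_F(t):
            return 0.0
    else:
        S_G, S_F = forcing.S_G, forcing.S_F

    product_form = adipose_glucose_product

    def rhs(t, y):
        (I, G_L, Y_L, P_L, R_L, A_L, S_L, T_L,
         G_M, Y_M, P_M, R_M, A_M, T_M, P,
         T_A, A_A_, L_A, G_A, T_CB, A_NB, T_LB, G_B) = y

        # shared fluxes
        glucokinase = v_LG * G_L / (k_LG + G_L)
        hexokinase_L = (v_LH * G_L / (k_LH + G_L)) / (1.0 + k_rep * P_L)
        glycogen_L = (0.5 * k_yl * I * P_L
                      * (1.0 + tanh((l_max - Y_L) / c_0))
                      - beta_L / (1.0 + k_dl * I) * Y_L / (Y_L + y_0))
        lipogenesis = beta_6 * R_L / (1.0 + k_p6 * I)
        secpool_in = v_6 * A_L / (k_6 + A_L)
        storage_out = v_10 * T_L / (k_10 + T_L)          # v19
        storage_in = v_8 * A_L / (k_8 + A_L)             # v21
        F_I = k_12 * tanh((v_12 - I) / k_13) + k_14
        vldl = F_I * v_9 * T_L / (k_9 + T_L)             # v24
        hexokinase_M = (v_MH * G_M / (k_MH + G_M)) / (1.0 + k_rep * P_M)
        glycogen_M = (0.5 * k_ym * I * P_M
                      * (1.0 + tanh((m_max - Y_M) / c_0))
                      - beta_M / (1.0 + k_dy * I) * Y_M / (Y_M + y_0))
        muscle_glc = (1.0 + k_gi * I) * (k_gm * G_B - k_gm2 * G_M)  # v25
        muscle_tag = m_s * I * A_M - m_e                  # v30
        adipo_ester = k_aa * I * A_A_ * G_A               # v36
        lipolysis = beta_f / (1.0 + k_ft * I * I)         # v37
        chylo_adipo = k_a * (1.0 + k_ai * I) * T_CB       # v38/v44/v45
        if product_form:
            adipo_glc = d_ba * (1.0 + k_ga * I) * G_B * G_A
        else:
            adipo_glc = d_ba * (1.0 + k_ga * I) * (G_B - G_A)  # v42

        dI = k_11 + k_22 * erf((G_B - v_thr) / c_c) - k_d * I
        dG_L = (S_G(t) - k_gl * G_L + k_gl2 * G_B - glucokinase
                - hexokinase_L + k_61 * P_L) / aL
        dY_L = glycogen_L / aL
        dP_L = (-glycogen_L - k_p * I * P_L + k_gp * L_A + lipogenesis
                + glucokinase + hexokinase_L - k_61 * P_L) / aL
        dR_L = (k_pp * R_M + 2.0 * mu_b + k_p * I * P_L - lipogenesis
                - k_al * I * R_L) / aL
        dA_L = (3.0 * k_cl * T_CB + k_bl * A_NB + 3.0 * k_r * T_LB
                + k_al * I * R_L - 3.0 * secpool_in + 3.0 * storage_out
                - 3.0 * storage_in - k_7 * A_L / (1.0 + k_5 * I)) / aL
        dS_L = (secpool_in - k_9a * S_L) / aL
        dT_L = (storage_in - vldl - storage_out) / aL
        dG_M = (muscle_glc - hexokinase_M) / aM
        dY_M = glycogen_M / aM
        dP_M = (hexokinase_M - glycogen_M - k_6p * I * P_M) / aM
        dR_M = (k_6p * I * P_M - k_pp * R_M - mu_3 * R_M * I * P) / aM
        dA_M = (-3.0 * muscle_tag + 3.0 * k_cm * T_CB + k_bm * A_NB
                + 3.0 * k_t * T_LB - mu_4 * A_M * P) / aM
        dT_M = muscle_tag / aM
        dP = mu_amp - mu_4 * A_M * P - mu_3 * R_M * I * P
        dT_A = (adipo_ester - lipolysis) / aA
        dA_A = (-3.0 * adipo_ester + 3.0 * chylo_adipo + 3.0 * k_ba * T_LB
                + k_na * A_NB) / aA
        dL_A = (lipolysis - k_gp * L_A) / aA
        dG_A = (adipo_glc - adipo_ester) / aA
        dT_CB = S_F(t) - k_cm * T_CB - k_cl * T_CB - chylo_adipo
        dA_NB = (-k_bm * A_NB - k_bl * A_NB - k_na * A_NB
                 + 3.0 * lipolysis + 3.0 * chylo_adipo)
        dT_LB = (vldl + k_9a * S_L - k_r * T_LB - k_t * T_LB
                 - k_ba * T_LB)
        dG_B = (k_gl * G_L - k_gl2 * G_B - muscle_glc - adipo_glc - mu_1)

        return (dI, dG_L, dY_L, dP_L, dR_L, dA_L, dS_L, dT_L,
                dG_M, dY_M, dP_M, dR_M, dA_M, dT_M, dP,
                dT_A, dA_A, dL_A, dG_A, dT_CB, dA_NB, dT_LB, dG_B)

    return rhs


def _check_finite(state: Sequence[float]) -> None:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (len(STATE_NAMES),):
        raise ValueError(
            f"state must have {len(STATE_NAMES)} components, "
            f"got shape {arr.shape}")
    bad = ~np.isfinite(arr)
    if bad.any():
        names = [STATE_NAMES[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"non-finite state component(s): {', '.join(names)}")


def evaluate_rhs(state: Sequence[float], params: ParameterSet,
                 t: float = 0.0, forcing=None,
                 uniform_liver_volume: bool = False,
                 adipose_glucose_product: bool = False) -> np.ndarray:
    """Time derivative of the 23 concentrations (units per minute).

    Deterministic: repeated calls on identical input are bit-identical.
    Raises ``ValueError`` naming the offending component for non-finite
    input.
    """
    _check_finite(state)
    rhs = make_rhs(params, forcing, uniform_liver_volume,
                   adipose_glucose_product)
    return np.array(rhs(float(t), tuple(float(x) for x in state)))


def registry_rhs(state: Sequence[float], params: ParameterSet,
                 t: float = 0.0, forcing=None,
                 uniform_liver_volume: bool = False,
                 registry: tuple[Reaction, ...] | None = None) -> np.ndarray:
    """Right-hand side assembled term by term from the reaction registry.

    Reference path for the flux-attribution closure check; not used for
    integration.
    """
    _check_finite(state)
    registry = REACTIONS if registry is None else registry
    st = State(*map(float, state))
    p = params.struct()
    acc = dict.fromkeys(STATE_NAMES, 0.0)
    for rxn in registry:
        rate = rxn.rate(st, p, float(t), forcing)
        for name, factor in rxn.stoich.items():
            acc[name] += factor * rate
    vol = _volume_factors(p, uniform_liver_volume)
    return np.array([acc[name] / vol[name] for name in STATE_NAMES])


def reaction_rates(state: Sequence[float], params: ParameterSet,
                   t: float = 0.0, forcing=None,
                   registry: tuple[Reaction, ...] | None = None
                   ) -> dict[str, float]:
    """All 45 registry fluxes at one state, keyed ``v1`` … ``v45``."""
    _check_finite(state)
    registry = REACTIONS if registry is None else registry
    st = State(*map(float, state))
    p = params.struct()
    return {rxn.rid: rxn.rate(st, p, float(t), forcing) for rxn in registry}


def initial_state(scenario) -> np.ndarray:
    """Default initial concentrations with scenario-supplied plasma values.

    ``scenario`` needs attributes ``G_B0`` and ``T_LB0`` (mmol/L), e.g. a
    :class:`hepfast.menu_conversion.MealScenario`.  Chylomicron TAG and
    muscle AMP start at zero.
    """
    g_b0 = float(scenario.G_B0)
    t_lb0 = float(scenario.T_LB0)
    if g_b0 < 0 or t_lb0 < 0:
        raise ValueError(
            f"scenario concentrations must be non-negative "
            f"(G_B0={g_b0}, T_LB0={t_lb0})")
    values = dict(DEFAULT_INITIAL)
    values["G_B"] = g_b0
    values["T_LB"] = t_lb0
    return np.array([values[name] for name in STATE_NAMES], dtype=float)


# --------------------------------------------------------------------------
# Units audit
# --------------------------------------------------------------------------

def units_report() -> list[dict[str, str]]:
    """Known dimensional inconsistencies of the documented constants.

    The model is implemented with the printed magnitudes; this curated
    report flags the places where the declared unit of a constant does not
    close dimensionally against the balance it enters.  Flagged, not fixed.
    """
    return [
        {"where": "v2 (insulin balance)", "parameter": "k_d",
         "issue": "declared L/mmol but acts as a first-order rate (1/min) "
         "on insulin in pmol/L; the printed magnitude 1.733e14 forces "
         "insulin onto a quasi-steady state I = v1/k_d"},
        {"where": "v1 (insulin balance)", "parameter": "k_11/k_22",
         "issue": "declared mmol/min but enter a pmol/L balance with no "
         "volume factor"},
        {"where": "v18 (liver TAG uptake)", "parameter": "k_r",
         "issue": "declared mmol; acts as a first-order rate (1/min) on "
         "T_LB"},
        {"where": "v4/v5 (liver-plasma glucose exchange)",
         "parameter": "k_gl/k_gl2",
         "issue": "declared mmol/L; act as first-order rates (1/min)"},
        {"where": "v9 (liver glycogen turnover)", "parameter": "l_max",
         "issue": "declared mmol but compared with the concentration Y_L "
         "(mmol/L) inside tanh"},
        {"where": "v27 (muscle glycogen turnover)", "parameter": "m_max",
         "issue": "declared mmol but compared with Y_M (mmol/L)"},
        {"where": "v1 (insulin secretion)", "parameter": "v",
         "issue": "declared mmol ('rate of glycogen transport') but acts "
         "as the plasma-glucose threshold (mmol/L) of the erf argument"},
        {"where": "liver pyruvate balance", "parameter": "mu_b",
         "issue": "appears twice in the printed balance (implemented as "
         "printed, net factor 2)"},
        {"where": "muscle/adipose balances", "parameter": "alpha_L",
         "issue": "printed with the liver volume on every compartmental "
         "balance; implemented with each compartment's own volume "
         "(uniform_liver_volume=True restores the literal print)"},
        {"where": "v30 (muscle TAG turnover)", "parameter": "m_s/m_e",
         "issue": "dimensionless constants act as fluxes (mmol/min); the "
         "same processes also have unused constants mu_s/mu_e"},
    ]
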