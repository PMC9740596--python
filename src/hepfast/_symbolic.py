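"""Symbolic form of the balance system (sympy).

Single symbolic source for two consumers: the SBML exporter (content
MathML kinetic laws) and the integrator (an analytic Jacobian — the
finite-difference Jacobian is unreliable on the insulin quasi-steady
manifold, where perturbing I by the absolute tolerance is many orders of
magnitude larger than I itself).

The test suite checks the symbolic rates against the registry lambdas
numerically, so the two representations cannot drift apart silently.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .model_core import (PARAM_NAMES, REACTIONS, STATE_COMPARTMENT,
                         STATE_NAMES)

__all__ = ["state_symbols", "param_symbols", "symbolic_rates",
           "symbolic_rhs", "jacobian_function"]


@lru_cache(maxsize=1)
def _symbols():
    import sympy as sp
    st = {name: sp.Symbol(name) for name in STATE_NAMES}
    pr = {name: sp.Symbol(name) for name in PARAM_NAMES}
    return st, pr


def state_symbols():
    return dict(_symbols()[0])


def param_symbols():
    return dict(_symbols()[1])


@lru_cache(maxsize=1)
def symbolic_rates():
    """Sympy expression per registry reaction (bolus mode: v3 = v43 = 0).

    The dietary inputs are state-independent, so the Jacobian derived from
    the bolus form is exact for every forcing mode.
    """
    import sympy as sp
    s, p = _symbols()
    F_I = p["k_12"] * sp.tanh((p["v_12"] - s["I"]) / p["k_13"]) + p["k_14"]
    chylo = p["k_a"] * (1 + p["k_ai"] * s["I"]) * s["T_CB"]
    return {
        "v1": p["k_11"] + p["k_22"] * sp.erf((s["G_B"] - p["v"]) / p["c_c"]),
        "v2": p["k_d"] * s["I"],
        "v3": sp.Integer(0),
        "v4": p["k_gl"] * s["G_L"],
        "v5": p["k_gl2"] * s["G_B"],
        "v6": p["v_LG"] * s["G_L"] / (p["k_LG"] + s["G_L"]),
        "v7": p["v_LH"] * s["G_L"] / (p["k_LH"] + s["G_L"])
        / (1 + p["k_rep"] * s["P_L"]),
        "v8": p["k_61"] * s["P_L"],
        "v9": sp.Rational(1, 2) * p["k_yl"] * s["I"] * s["P_L"]
        * (1 + sp.tanh((p["l_max"] - s["Y_L"]) / p["c_0"]))
        - p["beta_L"] / (1 + p["k_dl"] * s["I"])
        * s["Y_L"] / (s["Y_L"] + p["y_0"]),
        "v10": p["k_p"] * s["I"] * s["P_L"],
        "v11": p["k_gp"] * s["L_A"],
        "v12": p["beta_6"] * s["R_L"] / (1 + p["k_p6"] * s["I"]),
        "v13": p["k_pp"] * s["R_M"],
        "v14": p["mu_b"],
        "v15": p["k_al"] * s["I"] * s["R_L"],
        "v16": p["k_cl"] * s["T_CB"],
        "v17": p["k_bl"] * s["A_NB"],
        "v18": p["k_r"] * s["T_LB"],
        "v19": p["v_10"] * s["T_L"] / (p["k_10"] + s["T_L"]),
        "v20": p["v_6"] * s["A_L"] / (p["k_6"] + s["A_L"]),
        "v21": p["v_8"] * s["A_L"] / (p["k_8"] + s["A_L"]),
        "v22": p["k_7"] * s["A_L"] / (1 + p["k_5"] * s["I"]),
        "v23": p["k_9a"] * s["S_L"],
        "v24": F_I * p["v_9"] * s["T_L"] / (p["k_9"] + s["T_L"]),
        "v25": (1 + p["k_gi"] * s["I"])
        * (p["k_gm"] * s["G_B"] - p["k_gm2"] * s["G_M"]),
        "v26": p["v_MH"] * s["G_M"] / (p["k_MH"] + s["G_M"])
        / (1 + p["k_rep"] * s["P_M"]),
        "v27": sp.Rational(1, 2) * p["k_ym"] * s["I"] * s["P_M"]
        * (1 + sp.tanh((p["m_max"] - s["Y_M"]) / p["c_0"]))
        - p["beta_M"] / (1 + p["k_dy"] * s["I"])
        * s["Y_M"] / (s["Y_M"] + p["y_0"]),
        "v28": p["k_6p"] * s["I"] * s["P_M"],
        "v29": p["mu_3"] * s["R_M"] * s["I"] * s["P"],
        "v30": p["m_s"] * s["I"] * s["A_M"] - p["m_e"],
        "v31": p["mu_4"] * s["A_M"] * s["P"],
        "v32": p["k_cm"] * s["T_CB"],
        "v33": p["k_bm"] * s["A_NB"],
        "v34": p["k_t"] * s["T_LB"],
        "v35": p["mu_amp"],
        "v36": p["k_aa"] * s["I"] * s["A_A"] * s["G_A"],
        "v37": p["beta_f"] / (1 + p["k_ft"] * s["I"] ** 2),
        "v38": chylo,
        "v39": p["k_ba"] * s["T_LB"],
        "v40": p["k_na"] * s["A_NB"],
        "v41": p["mu_1"],
        "v42": p["d_ba"] * (1 + p["k_ga"] * s["I"])
        * (s["G_B"] - s["G_A"]),
        "v43": sp.Integer(0),
        "v44": chylo,
        "v45": chylo,
    }


@lru_cache(maxsize=2)
def symbolic_rhs(uniform_liver_volume: bool = False):
    """The 23 balance right-hand sides assembled from the symbolic rates."""
    import sympy as sp
    s, p = _symbols()
    rates = symbolic_rates()
    stoich = {r.rid: r.stoich for r in REACTIONS}
    acc = {name: sp.Integer(0) for name in STATE_NAMES}
    for rid, expr in rates.items():
        for name, factor in stoich[rid].items():
            acc[name] += factor * expr
    out = []
    for name in STATE_NAMES:
        comp = STATE_COMPARTMENT[name]
        if name in ("I", "P") or comp == "plasma":
            vol = 1
        elif comp == "liver" or uniform_liver_volume:
            vol = p["alpha_L"]
        elif comp == "muscle":
            vol = p["alpha_M"]
        else:
            vol = p["alpha_A"]
        out.append(acc[name] / vol)
    return sp.Matrix(out)


@lru_cache(maxsize=2)
def jacobian_function(uniform_liver_volume: bool = False):
    """Lambdified analytic Jacobian ``J(y, param_values) -> (23, 23)``."""
    import sympy as sp
    s, p = _symbols()
    rhs = symbolic_rhs(uniform_liver_volume)
    state_syms = [s[name] for name in STATE_NAMES]
    param_syms = [p[name] for name in PARAM_NAMES]
    J = rhs.jacobian(state_syms)
    fn = sp.lambdify((state_syms, param_syms), J, modules="numpy")

    def jac(y, param_values):
        return np.asarray(fn(y, param_values), dtype=float)

    return jac
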