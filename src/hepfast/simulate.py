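"""Stiff integration of the lipid metabolism balances for meal scenarios.

A meal is represented by default as a bolus: the meal-derived glucose and
TAG appear as elevated plasma concentrations at t = 0 and the dietary input
fluxes S_G(t), S_F(t) are identically zero afterwards.  An exponential
forcing mode is provided for completeness (dose spread over an exponential
decay with the dietary time scales alpha_G/alpha_F).

The printed rate constants span roughly twenty orders of magnitude — the
insulin degradation constant alone forces a quasi-steady insulin manifold —
so integration uses a variable-order stiff-capable method (LSODA) with
tight default tolerances and dense output.  Negative excursions are
reported as diagnostics, never clipped: clamping would silently change the
model that is being analysed.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

from . import model_core
from .menu_conversion import Menu, menu_to_scenarios
from .model_core import ParameterSet, STATE_NAMES, initial_state, make_rhs, \
    reaction_rates

__all__ = [
    "MealForcing",
    "BOLUS",
    "Trajectory",
    "SolverError",
    "integrate",
    "batch_states",
    "run_meal_scenarios",
    "observables_at",
    "trajectory_to_frame",
]

#: Observables reported for meal-scenario runs.
PLASMA_OBSERVABLES = ("G_B", "I", "A_NB", "T_LB")

#: Default solver settings for single trajectories.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SolverError(RuntimeError):
    """Integration failure carrying the failing time and last valid state."""

    def __init__(self, message, t_fail=None, last_state=None):
        super().__init__(message)
        self.t_fail = t_fail
        self.last_state = last_state


@dataclass(frozen=True)
class MealForcing:
    """Dietary input fluxes S_G(t), S_F(t).

    ``bolus`` mode (default): both are zero for all t — the meal enters
    through the initial conditions only.  ``exponential`` mode: the doses
    (mmol) enter as ``dose/tau * exp(-t/tau)`` with time scales ``alpha_G``
    and ``alpha_F`` (minutes), non-negative and integrable.
    """

    mode: str = "bolus"
    glucose_dose: float = 0.0
    fat_dose: float = 0.0
    alpha_G: float = 2.0
    alpha_F: float = 2.0

    def __post_init__(self):
        if self.mode not in ("bolus", "exponential"):
            raise ValueError(f"unknown forcing mode {self.mode!r}")
        if self.mode == "exponential":
            if self.glucose_dose < 0 or self.fat_dose < 0:
                raise ValueError("doses must be non-negative")
            if self.alpha_G <= 0 or self.alpha_F <= 0:
                raise ValueError("decay scales must be positive")

    def S_G(self, t: float) -> float:
        if self.mode == "bolus" or t < 0:
            return 0.0
        return self.glucose_dose / self.alpha_G * math.exp(-t / self.alpha_G)

    def S_F(self, t: float) -> float:
        if self.mode == "bolus" or t < 0:
            return 0.0
        return self.fat_dose / self.alpha_F * math.exp(-t / self.alpha_F)


BOLUS = MealForcing()


@dataclass
class Trajectory:
    """Solution of the balances on a time grid (time x 23 states)."""

    t: np.ndarray
    y: np.ndarray                       # shape (len(t), 23)
    names: tuple[str, ...] = STATE_NAMES
    scenario: str = ""
    solver: dict = field(default_factory=dict)
    _dense: Callable | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.t.size, len(self.names)):
            raise ValueError("state matrix shape does not match grid")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite trajectory entries")

    def state_at(self, t_f: float) -> np.ndarray:
        """State at ``t_f``, from dense output when available."""
        if not (self.t[0] <= t_f <= self.t[-1]):
            raise ValueError(f"t_f={t_f} outside trajectory span "
                             f"[{self.t[0]}, {self.t[-1]}]")
        if self._dense is not None:
            return np.asarray(self._dense(t_f), dtype=float)
        out = np.empty(len(self.names))
        for j in range(len(self.names)):
            out[j] = np.interp(t_f, self.t, self.y[:, j])
        return out

    def series(self, name: str) -> np.ndarray:
        return self.y[:, self.names.index(name)]

    @property
    def negative_excursions(self) -> dict[str, float]:
        """Most negative value reached per state (diagnostic only)."""
        mins = self.y.min(axis=0)
        return {n: float(m) for n, m in zip(self.names, mins) if m < 0}

    def run_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.t.tobytes())
        h.update(self.y.tobytes())
        return h.hexdigest()[:16]


def integrate(params: ParameterSet, init: Sequence[float],
              t_grid: Sequence[float], forcing: MealForcing = BOLUS,
              method: str = "LSODA", rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, dense: bool = True,
              scenario: str = "",
              uniform_liver_volume: bool = False) -> Trajectory:
    """Integrate the balances and sample the solution on ``t_grid``.

    The grid must start at 0 and increase strictly; the first trajectory
    row equals ``init`` exactly.  Solver failures raise
    :class:`SolverError` with the failing time and last valid state;
    non-finite blow-ups are reported, not clipped.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    init = np.asarray(init, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or t_grid[0] != 0.0:
        raise ValueError("t_grid must be 1-D and start at 0")
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    model_core._check_finite(init)

    meta = {"method": method, "rtol": rtol, "atol": atol,
            "forcing": forcing.mode}
    if t_grid.size == 1:
        return Trajectory(t_grid, init[None, :], scenario=scenario,
                          solver=meta)

    rhs = make_rhs(params, forcing, uniform_liver_volume)
    jac = None
    if method in ("LSODA", "BDF", "Radau"):
        from ._symbolic import jacobian_function
        jac_eval = jacobian_function(uniform_liver_volume)
        pv = np.array(params.struct(), dtype=float)

        def jac(t, y):
            return jac_eval(y, pv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), init, method=method,
                        t_eval=t_grid, rtol=rtol, atol=atol,
                        dense_output=dense, jac=jac)
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        last = sol.y[:, -1] if sol.t.size else init
        raise SolverError(
            f"integration failed at t={t_fail:.6g} min: {sol.message}",
            t_fail=t_fail, last_state=np.asarray(last))
    y = sol.y.T.copy()
    if not np.all(np.isfinite(y)):
        bad = int(np.nonzero(~np.isfinite(y).all(axis=1))[0][0])
        raise SolverError(
            f"non-finite state at t={t_grid[bad]:.6g} min",
            t_fail=float(t_grid[bad]), last_state=y[max(bad - 1, 0)])
    y[0] = init  # exact initial row
    meta.update(nfev=int(sol.nfev), njev=int(getattr(sol, "njev", 0) or 0),
                n_steps=int(sol.t.size))
    return Trajectory(t_grid, y, scenario=scenario, solver=meta,
                      _dense=sol.sol if dense else None)


def batch_states(param_structs: Sequence, init: Sequence[float],
                 t_points: Sequence[float], forcing: MealForcing = BOLUS,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 mxstep: int = 2500, use_jacobian: bool = True,
                 uniform_liver_volume: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """States at ``t_points`` for many parameter draws (screening path).

    One LSODA integration per draw (``scipy.integrate.odeint``) with the
    analytic Jacobian, the horizons read from a single solve.  Returns
    ``(states, ok)`` with ``states`` of shape (n_draws, len(t_points), 23)
    and ``ok`` a boolean success mask; failed draws hold NaN and are left
    to the caller's imputation rule.

    ``mxstep`` doubles as a fast-fail bound: draws whose trajectory runs
    into the model's finite-time pole (the hexokinase inhibition factor
    1/(1 + k_rep*P_L) diverges once P_L reaches -1/k_rep, which happens
    for a substantial share of wide log-span draws) stall the integrator
    and are cut off after ``mxstep`` steps.  Successful draws need about
    1200 steps at the default tolerances.
    """
    t_points = np.asarray(t_points, dtype=float)
    if np.any(t_points <= 0) or np.any(np.diff(t_points) <= 0):
        raise ValueError("t_points must be positive and strictly "
                         "increasing")
    init = np.asarray(init, dtype=float)
    t_solve = np.concatenate([[0.0], t_points])

    jac_eval = None
    if use_jacobian:
        from ._symbolic import jacobian_function
        jac_eval = jacobian_function(uniform_liver_volume)

    n = len(param_structs)
    out = np.full((n, t_points.size, len(STATE_NAMES)), np.nan)
    ok = np.zeros(n, dtype=bool)
    dummy = _StructParams.__new__(_StructParams)
    for k, p in enumerate(param_structs):
        dummy._struct = p
        rhs = make_rhs(dummy, forcing, uniform_liver_volume)
        if jac_eval is not None:
            pv = np.array(p, dtype=float)

            def dfun(t, y, _pv=pv):
                return jac_eval(y, _pv)
        else:
            dfun = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                y, info = odeint(rhs, init, t_solve, Dfun=dfun,
                                 tfirst=True, rtol=rtol, atol=atol,
                                 mxstep=mxstep, full_output=True)
            except Exception:
                continue
        if info["message"] != "Integration successful." \
                or not np.all(np.isfinite(y)):
            continue
        out[k] = y[1:]
        ok[k] = True
    return out, ok


class _StructParams:
    """Minimal ParameterSet stand-in wrapping a prebuilt struct."""

    def struct(self):
        return self._struct


def run_meal_scenarios(menus: Sequence[Menu], params: ParameterSet | None
                       = None, horizon: float = 500.0, n_grid: int = 501,
                       fat_factor: float | None = None,
                       rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                       ) -> dict[tuple, Trajectory]:
    """One trajectory per (menu, meal): 4 menus x 4 meals = 16 runs.

    Initial plasma glucose and TAG come from the menu via the conversion
    rules; the fat conversion factor is fitted on the menus themselves
    unless supplied.  Keys are ``(menu identifier, meal label)``.
    """
    params = params or model_core.default_parameters()
    if fat_factor is None:
        from .synthetic_menus import fitted_fat_factor
        fat_factor = fitted_fat_factor()
    t_grid = np.linspace(0.0, horizon, n_grid)
    out = {}
    for menu in menus:
        scenarios = menu_to_scenarios(menu, fat_factor)
        for label, scen in scenarios.items():
            init = initial_state(scen)
            out[(menu.identifier, label)] = integrate(
                params, init, t_grid, rtol=rtol, atol=atol,
                scenario=f"menu {menu.identifier} {label}")
    return out


def observables_at(trajectory: Trajectory, t_f: float,
                   params: ParameterSet, forcing: MealForcing = BOLUS
                   ) -> tuple[dict[str, float], dict[str, float]]:
    """Metabolite and reaction-rate observables at one horizon.

    Metabolites are interpolated from the solver's dense output at ``t_f``;
    reaction rates are evaluated on that state through the registry.
    Returns ``(metabolites, rates)`` dictionaries.
    """
    state = trajectory.state_at(t_f)
    metabolites = dict(zip(trajectory.names, map(float, state)))
    rates = reaction_rates(state, params, t=t_f, forcing=forcing)
    return metabolites, rates


def trajectory_to_frame(trajectories: Mapping[tuple, Trajectory],
                        observables: Sequence[str] = PLASMA_OBSERVABLES
                        ) -> pd.DataFrame:
    """Tidy long-format export: time, variable, value, scenario."""
    rows = []
    for key, traj in trajectories.items():
        label = traj.scenario or str(key)
        for name in observables:
            series = traj.series(name)
            rows.append(pd.DataFrame({
                "time_min": traj.t, "variable": name, "value": series,
                "scenario": label}))
    return pd.concat(rows, ignore_index=True)


def solver_metadata_json(traj: Trajectory, seed=None) -> str:
    meta = dict(traj.solver)
    meta["scenario"] = traj.scenario
    meta["run_hash"] = traj.run_hash()
    if seed is not None:
        meta["seed"] = seed
    return json.dumps(meta, indent=2, sort_keys=True)
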