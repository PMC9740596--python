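"""Stiff integration: fidelity, determinism, solver robustness."""

import numpy as np
import pytest

from hepfast import model_core as mc
from hepfast import simulate as sim


@pytest.fixture(scope="module")
def lunch1_traj(params):
    class S:
        G_B0, T_LB0 = 3.2, 9.1
    init = mc.initial_state(S)
    t = np.linspace(0.0, 500.0, 251)
    return sim.integrate(params, init, t, scenario="menu 1 lunch"), init


def test_grid_of_single_point_returns_init(params, lunch1_init):
    traj = sim.integrate(params, lunch1_init, [0.0])
    assert traj.t.tolist() == [0.0]
    assert (traj.y[0] == lunch1_init).all()


def test_first_row_is_initial_state_exactly(lunch1_traj):
    traj, init = lunch1_traj
    assert (traj.y[0] == init).all()


def test_all_sources_off_gives_constant_trajectory(lunch1_init):
    """Zeroing every rate constant freezes the state."""
    p = mc.default_parameters()
    zeros = {name: 0.0 for name in p
             if not name.startswith("alpha")
             and name not in ("c_0", "c_c", "k_13", "y_0", "k_6", "k_8",
                              "k_9", "k_10", "k_LG", "k_LH", "k_MH",
                              "l_max", "m_max", "v", "v_12", "k_rep")}
    quiet = p.replace(**zeros)
    dy = mc.evaluate_rhs(lunch1_init, quiet)
    assert np.allclose(dy, 0.0)
    traj = sim.integrate(quiet, lunch1_init, np.linspace(0, 100, 11))
    assert np.allclose(traj.y, lunch1_init[None, :], atol=1e-8)


def test_insulin_subsystem_matches_closed_form():
    """dI/dt = a - k*I alone matches I(t) = a/k + (I0 - a/k) e^{-kt}."""
    p = mc.default_parameters()
    a, k = 5.0, 0.05
    sub = {name: 0.0 for name in p
           if not name.startswith("alpha")
           and name not in ("c_0", "c_c", "k_13", "y_0", "k_6", "k_8",
                            "k_9", "k_10", "k_LG", "k_LH", "k_MH",
                            "l_max", "m_max", "v", "v_12", "k_rep")}
    sub.update(k_11=a, k_d=k)
    p_sub = p.replace(**sub)
    # erf((G_B - v)/c_c) = erf(large) ~ 1 would add k_22; k_22 = 0 here so
    # secretion is the constant a
    class S:
        G_B0, T_LB0 = 10.0, 0.0
    init = mc.initial_state(S)
    t = np.linspace(0.0, 200.0, 41)
    traj = sim.integrate(p_sub, init, t)
    I0 = init[mc.STATE_NAMES.index("I")]
    expected = a / k + (I0 - a / k) * np.exp(-k * t)
    assert np.allclose(traj.series("I"), expected, rtol=1e-6, atol=1e-6)


def test_deterministic_repeatability(params, lunch1_init):
    t = np.linspace(0.0, 200.0, 21)
    a = sim.integrate(params, lunch1_init, t)
    b = sim.integrate(params, lunch1_init, t)
    assert (a.y == b.y).all()
    assert a.run_hash() == b.run_hash()


def test_solver_independence(params, lunch1_init):
    """LSODA and BDF agree on all 23 states at t = 500 within 0.5%."""
    t = np.array([0.0, 500.0])
    a = sim.integrate(params, lunch1_init, t, method="LSODA")
    b = sim.integrate(params, lunch1_init, t, method="BDF")
    scale = np.maximum(np.abs(a.y[-1]), 1e-6)
    assert np.max(np.abs(a.y[-1] - b.y[-1]) / scale) < 5e-3


def test_tolerance_robustness(params, lunch1_init):
    """Tenfold tighter tolerances move no state by more than 0.1%."""
    t = np.array([0.0, 100.0, 500.0])
    a = sim.integrate(params, lunch1_init, t)
    b = sim.integrate(params, lunch1_init, t, rtol=1e-9, atol=1e-11)
    scale = np.maximum(np.abs(b.y[-1]), 1e-6)
    assert np.max(np.abs(a.y[-1] - b.y[-1]) / scale) < 1e-3


def test_bolus_conservation_of_plasma_glucose(lunch1_init):
    """With every plasma-glucose exchange off, G_B stays constant."""
    p = mc.default_parameters().replace(
        k_gl=0, k_gl2=0, k_gm=0, k_gm2=0, d_ba=0, mu_1=0)
    traj = sim.integrate(p, lunch1_init, np.linspace(0, 200, 21))
    assert np.allclose(traj.series("G_B"), 3.2, atol=1e-7)


def test_observables_at_consistency(params, lunch1_traj):
    """v19 from observables equals its scalar recomputation."""
    traj, _ = lunch1_traj
    metabolites, rates = sim.observables_at(traj, 100.0, params)
    T_L = metabolites["T_L"]
    assert rates["v19"] == pytest.approx(
        params["v_10"] * T_L / (params["k_10"] + T_L), rel=1e-12)
    met0, _ = sim.observables_at(traj, 0.0, params)
    assert met0["G_B"] == pytest.approx(3.2)


def test_observables_outside_span_rejected(params, lunch1_traj):
    traj, _ = lunch1_traj
    with pytest.raises(ValueError):
        sim.observables_at(traj, 600.0, params)


def test_invalid_grid_rejected(params, lunch1_init):
    with pytest.raises(ValueError):
        sim.integrate(params, lunch1_init, [10.0, 20.0])   # not from 0
    with pytest.raises(ValueError):
        sim.integrate(params, lunch1_init, [0.0, 5.0, 5.0])


def test_forcing_modes():
    bolus = sim.MealForcing()
    assert bolus.S_G(10.0) == 0.0 and bolus.S_F(10.0) == 0.0
    expo = sim.MealForcing("exponential", glucose_dose=10.0, fat_dose=5.0,
                           alpha_G=2.0, alpha_F=2.0)
    # integrates to the dose
    t = np.linspace(0, 60, 6001)
    total = np.trapezoid([expo.S_G(x) for x in t], t)
    assert total == pytest.approx(10.0, rel=1e-3)
    assert all(expo.S_F(x) >= 0 for x in t)
    with pytest.raises(ValueError):
        sim.MealForcing("square")


def test_run_meal_scenarios_grid(params, menus, scenario_grid):
    """16 trajectories whose t = 0 plasma values match the scenario grid."""
    trajs = sim.run_meal_scenarios(menus, params, n_grid=26,
                                   rtol=1e-6, atol=1e-9)
    assert len(trajs) == 16
    for (menu_id, meal), traj in trajs.items():
        g, tlb = scenario_grid[(menu_id, meal)]
        assert traj.series("G_B")[0] == pytest.approx(g)
        assert traj.series("T_LB")[0] == pytest.approx(tlb)
    frame = sim.trajectory_to_frame(trajs)
    assert set(frame["variable"]) == {"G_B", "I", "A_NB", "T_LB"}
    assert frame["scenario"].nunique() == 16


def test_batch_states_matches_integrate(params, lunch1_init):
    """The screening path agrees with the reference integrator."""
    t_points = [10.0, 100.0, 500.0]
    states, ok = sim.batch_states([params.struct()], lunch1_init, t_points)
    assert ok.all()
    traj = sim.integrate(params, lunch1_init, [0.0] + t_points)
    scale = np.maximum(np.abs(traj.y[1:]), 1e-6)
    assert np.max(np.abs(states[0] - traj.y[1:]) / scale) < 1e-3
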