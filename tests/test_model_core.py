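"""Balance equations, parameter table and the 45-reaction registry."""

import math

import numpy as np
import pytest

from hepfast import model_core as mc


class TestParameters:
    def test_counts(self, params):
        assert len(params) == 81
        varied = [n for n in params if params.varied_for_fast(n)]
        assert len(varied) == 78
        assert set(mc.VARIED_ORDER) == set(varied)

    def test_documented_values(self, params):
        assert params["beta_L"] == 12.0
        assert params["k_11"] == 48.0
        assert params["beta_f"] == 0.117
        assert params["alpha_M"] == 26.4
        # corrected mantissa typo
        assert params["k_dl"] == 3.5e8

    def test_positive(self, params):
        assert all(v > 0 for _, v in params.items())

    def test_provenance_log(self, params):
        log = params.provenance_log()
        assert "k_dl" in log and "corrected" in log["k_dl"]
        assert "beta_G" in log

    def test_yaml_round_trip_bit_exact(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        back = mc.ParameterSet.from_yaml(str(path))
        for name, value in params.items():
            assert back[name] == value  # exact, not approx

    def test_replace_does_not_mutate(self, params):
        other = params.replace(beta_L=1.0)
        assert params["beta_L"] == 12.0 and other["beta_L"] == 1.0
        with pytest.raises(KeyError):
            params.replace(nonexistent=1.0)


class TestRegistry:
    def test_exactly_45_reactions(self):
        assert len(mc.REACTIONS) == 45
        assert mc.REACTION_IDS == tuple(f"v{i}" for i in range(1, 46))

    def test_flux_attribution_closure(self, params, rng):
        """Signed registry fluxes / alpha reproduce the assembled RHS."""
        for _ in range(30):
            y = rng.uniform(0.01, 60.0, len(mc.STATE_NAMES))
            a = mc.evaluate_rhs(y, params)
            b = mc.registry_rhs(y, params)
            assert np.allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_closure_uniform_volume_variant(self, params, rng):
        y = rng.uniform(0.1, 20.0, len(mc.STATE_NAMES))
        a = mc.evaluate_rhs(y, params, uniform_liver_volume=True)
        b = mc.registry_rhs(y, params, uniform_liver_volume=True)
        assert np.allclose(a, b, rtol=1e-12)

    def test_tag_to_ffa_stoichiometry_factor_three(self):
        """Every TAG->FFA conversion carries the factor 3 (3 FFA per TAG)."""
        expectations = {
            "v16": ("A_L", 3), "v18": ("A_L", 3), "v19": ("A_L", 3),
            "v32": ("A_M", 3), "v34": ("A_M", 3), "v37": ("A_NB", 3),
            "v39": ("A_A", 3), "v44": ("A_A", 3), "v45": ("A_NB", 3),
        }
        by_id = {r.rid: r for r in mc.REACTIONS}
        for rid, (state, factor) in expectations.items():
            assert by_id[rid].stoich[state] == factor
        # FFA -> TAG directions likewise consume 3 FFA
        assert by_id["v20"].stoich["A_L"] == -3
        assert by_id["v21"].stoich["A_L"] == -3
        assert by_id["v36"].stoich["A_A"] == -3

    def test_each_state_touched(self):
        touched = set()
        for r in mc.REACTIONS:
            touched.update(r.stoich)
        assert touched == set(mc.STATE_NAMES)


class TestRhs:
    def test_insulin_secretion_scalar_oracle(self, params, lunch1_init):
        """k_11 + k_22*erf((G_B - v)/c_c) at G_B = 3.2 -> 48*(1+erf(-1.52))."""
        rates = mc.reaction_rates(lunch1_init, params)
        expected = 48.0 * (1.0 + math.erf(-1.52))
        assert rates["v1"] == pytest.approx(expected, rel=1e-12)
        assert rates["v1"] == pytest.approx(1.5161521478, rel=1e-9)

    def test_glycogen_capacity_switch_at_lmax(self, params):
        """At Y_L = l_max the tanh factor is 1: half the maximal synthesis."""
        y = np.array(mc.initial_state(type("S", (), {"G_B0": 1.0,
                                                     "T_LB0": 1.0})))
        i_yl = mc.STATE_NAMES.index("Y_L")
        y[i_yl] = params["l_max"]
        st = mc.State(*y)
        p = params.struct()
        synthesis = 0.5 * p.k_yl * st.I * st.P_L * (
            1.0 + math.tanh((p.l_max - st.Y_L) / p.c_0))
        assert synthesis == pytest.approx(0.5 * p.k_yl * st.I * st.P_L)

    def test_plasma_ffa_balance_vanishes(self, params, lunch1_init):
        """With all exchange constants zero, dA_NB/dt = 0."""
        quiet = params.replace(k_bm=0, k_bl=0, k_na=0, beta_f=0, k_a=0)
        dy = mc.evaluate_rhs(lunch1_init, quiet)
        assert dy[mc.STATE_NAMES.index("A_NB")] == 0.0

    def test_v19_scalar_oracle(self, params, lunch1_init):
        """v_10*T_L/(k_10+T_L) at T_L = 40 -> 0.1*40/40.625."""
        rates = mc.reaction_rates(lunch1_init, params)
        assert rates["v19"] == pytest.approx(0.1 * 40 / (0.625 + 40),
                                             rel=1e-12)
        assert rates["v19"] == pytest.approx(0.09846, abs=5e-6)

    def test_rates_at_zero_insulin(self, params, lunch1_init):
        y = np.array(lunch1_init)
        y[mc.STATE_NAMES.index("I")] = 0.0
        rates = mc.reaction_rates(y, params)
        assert rates["v2"] == 0.0                      # k_d * I
        assert rates["v37"] == pytest.approx(0.117)    # beta_f at I = 0

    def test_deterministic_bit_identical(self, params, lunch1_init):
        a = mc.evaluate_rhs(lunch1_init, params, t=3.0)
        b = mc.evaluate_rhs(lunch1_init, params, t=3.0)
        assert (a == b).all()

    def test_nonfinite_input_named(self, params, lunch1_init):
        y = np.array(lunch1_init)
        y[mc.STATE_NAMES.index("T_A")] = np.nan
        with pytest.raises(ValueError, match="T_A"):
            mc.evaluate_rhs(y, params)


class TestInitialState:
    def test_lunch_scenario(self, lunch1_init):
        names = mc.STATE_NAMES
        assert lunch1_init[names.index("G_B")] == 3.2
        assert lunch1_init[names.index("T_LB")] == 9.1
        assert lunch1_init[names.index("I")] == 60.0
        assert lunch1_init[names.index("Y_L")] == 50.0
        assert lunch1_init[names.index("T_CB")] == 0.0
        assert lunch1_init[names.index("P")] == 0.0

    def test_breakfast_scenario(self):
        class S:
            G_B0, T_LB0 = 44.7, 1.6
        y = mc.initial_state(S)
        assert y[mc.STATE_NAMES.index("G_B")] == 44.7
        assert y[mc.STATE_NAMES.index("T_LB")] == 1.6

    def test_zero_scenario_keeps_defaults(self):
        class S:
            G_B0, T_LB0 = 0.0, 0.0
        y = mc.initial_state(S)
        for i, name in enumerate(mc.STATE_NAMES):
            if name in ("G_B", "T_LB"):
                assert y[i] == 0.0
            else:
                assert y[i] == mc.DEFAULT_INITIAL[name]

    def test_negative_rejected(self):
        class S:
            G_B0, T_LB0 = -0.1, 5.0
        with pytest.raises(ValueError):
            mc.initial_state(S)


def test_units_report_flags_known_mismatches():
    report = mc.units_report()
    flagged = {entry["parameter"] for entry in report}
    assert "k_d" in flagged
    assert any("mu_b" in p for p in flagged)
    assert all({"where", "parameter", "issue"} <= set(e) for e in report)
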