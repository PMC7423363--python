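"""Reactor configuration, analytical stepping, and community simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msh import (
    ReactorConfig,
    ReactorState,
    o2_saturation_uM,
    oxygen_quasi_steady,
    residence_time_h,
    simulate,
    sparge_fraction,
    step_biomass,
    step_metabolite,
    step_oxygen,
)
from msh.fba import KineticParams
from msh.sweep import default_initial_state
from msh.synth import DEXTRAN_FEED_MM, make_single_substrate_model


class TestConfigHelpers:
    def test_residence_time(self):
        assert residence_time_h(200.0, 40.0) == pytest.approx(5.0)

    def test_sparge_fraction(self):
        assert sparge_fraction(1.7, 50.0) == pytest.approx(0.034)

    def test_o2_saturation_calibration(self):
        # 6.056 mg/L air-saturated at 37 C scaled to a 3.4% O2 sparge
        assert o2_saturation_uM(0.034) == pytest.approx(30.714, abs=1e-3)

    def test_config_derived_quantities(self):
        cfg = ReactorConfig()
        assert cfg.dilution_rate == pytest.approx(0.2)
        assert cfg.residence_time == pytest.approx(5.0)
        assert cfg.s_star == pytest.approx(30.714e-3, rel=1e-4)
        # oxygen inflow maps linearly onto the saturation concentration
        assert cfg.with_oxygen_inflow(3.4).s_star == pytest.approx(2 * cfg.s_star)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReactorConfig(volume_L=0.0)
        with pytest.raises(ValueError):
            ReactorConfig(dt_h=-0.01)
        with pytest.raises(ValueError):
            ReactorConfig(dextran_release_fraction=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ReactorConfig(s_feed={"glc_e": 3.0}, kla_per_h=10.0)
        path = tmp_path / "reactor.yaml"
        cfg.to_yaml(path)
        back = ReactorConfig.from_yaml(path)
        assert back == cfg


class TestStateValidation:
    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            ReactorState(0.0, {"aerobe": -1.0}, {}, 0.0)

    def test_negative_oxygen_rejected(self):
        with pytest.raises(ValueError):
            ReactorState(0.0, {}, {}, -1e-9)


def _rk4(x0, mu, D, T, n=20000):
    """Fine-step RK4 for dX/dt = (mu - D) X, the independent stepping oracle."""
    h = T / n
    x = x0
    f = lambda x: (mu - D) * x
    for _ in range(n):
        k1 = f(x)
        k2 = f(x + h / 2 * k1)
        k3 = f(x + h / 2 * k2)
        k4 = f(x + h * k3)
        x += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


class TestStepBiomass:
    def test_growth_balances_dilution(self):
        cfg = ReactorConfig()
        assert step_biomass(1.3, cfg.dilution_rate, cfg) == pytest.approx(1.3)

    def test_pure_washout(self):
        cfg = ReactorConfig(dt_h=5.0)
        assert step_biomass(1.0, 0.0, cfg) == pytest.approx(np.exp(-1.0), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        x0=st.floats(1e-6, 10.0),
        mu=st.floats(0.0, 1.5),
        D=st.floats(0.01, 1.0),
        dt=st.floats(0.001, 5.0),
    )
    def test_matches_ode_oracle(self, x0, mu, D, dt):
        """The analytic step equals fine-step integration of
        dX/dt = (mu - D) X; with mu constant within the step it is exact."""
        cfg = ReactorConfig(volume_L=1.0, flow_L_h=D, dt_h=dt)
        ours = step_biomass(x0, mu, cfg)
        ref = _rk4(x0, mu, D, dt)
        assert ours == pytest.approx(ref, rel=1e-10)


class TestStepMetabolite:
    def test_equilibrium_with_feed(self):
        cfg = ReactorConfig(dt_h=0.1)
        assert step_metabolite(5.0, [], cfg, feed_S=5.0) == pytest.approx(5.0)

    def test_dilution_only(self):
        # no biomass, S0 = 0, feed 5 mM, D*dt = 0.2 -> 1.0 mM
        cfg = ReactorConfig(volume_L=1.0, flow_L_h=0.2, dt_h=1.0)
        assert step_metabolite(0.0, [(0.0, 0.0, 0.0)], cfg, feed_S=5.0) == pytest.approx(1.0)

    def test_singular_limit_matches_series(self):
        """As mu -> D the consumption term tends to v*X0*dt."""
        cfg = ReactorConfig(dt_h=0.05)
        D = cfg.dilution_rate
        v, x0 = -2.0, 0.5
        at_limit = step_metabolite(10.0, [(v, x0, D)], cfg)
        near = step_metabolite(10.0, [(v, x0, D + 1e-7)], cfg)
        expected = 10.0 + v * x0 * cfg.dt_h + D * (0.0 - 10.0) * cfg.dt_h
        assert at_limit == pytest.approx(expected, rel=1e-12)
        assert near == pytest.approx(at_limit, rel=1e-6)

    def test_floored_at_zero(self):
        cfg = ReactorConfig(dt_h=1.0)
        assert step_metabolite(0.1, [(-50.0, 1.0, 0.2)], cfg) == 0.0


class TestStepOxygen:
    def test_transfer_equilibrium(self):
        cfg = ReactorConfig(dt_h=0.1)
        assert step_oxygen(cfg.s_star, [], cfg) == pytest.approx(cfg.s_star)

    def test_transfer_from_zero(self):
        # kLa*dt = 0.5, S* = 0.03 mM -> 0.015 mM
        cfg = ReactorConfig(kla_per_h=5.0, dt_h=0.1, s_star_mM=0.03)
        assert step_oxygen(0.0, [], cfg) == pytest.approx(0.015)

    def test_consumption_clamped_at_zero(self):
        cfg = ReactorConfig(kla_per_h=1.0, dt_h=0.1, s_star_mM=0.03)
        assert step_oxygen(0.01, [(-100.0, 1.0, 0.2)], cfg) == 0.0

    def test_optional_dilution_term(self):
        base = ReactorConfig(kla_per_h=0.0, dt_h=0.1, s_star_mM=0.03)
        with_dil = ReactorConfig(kla_per_h=0.0, dt_h=0.1, s_star_mM=0.03, o2_dilution=True)
        s0 = 0.02
        assert step_oxygen(s0, [], base) == pytest.approx(s0)
        assert step_oxygen(s0, [], with_dil) == pytest.approx(s0 * (1 - 0.2 * 0.1))

    def test_quasi_steady_balance(self):
        cfg = ReactorConfig(kla_per_h=42.0)
        # no consumers -> saturation
        assert oxygen_quasi_steady([], cfg) == pytest.approx(cfg.s_star)
        # a strong consumer pulls O2 to the supply/affinity balance
        s = oxygen_quasi_steady([(0.3, 20.0, 20.0, 1e-4)], cfg)
        assert 0.0 < s < cfg.s_star
        demand = 0.3 * min(20.0, 20.0 * s / (1e-4 + s))
        assert demand == pytest.approx(42.0 * (cfg.s_star - s), rel=1e-8)


class TestSimulate:
    def test_no_exchange_relaxes_to_feed_and_washout(self, toy_models):
        """With all uptake shut off every metabolite relaxes monotonically
        to its feed level and biomass decays at exactly D."""
        dead = KineticParams()
        dead.default = type(dead.default)(0.0, 0.01)  # v_max = 0 everywhere
        cfg = ReactorConfig(s_feed={"glc_e": 2.0, "dex_e": 0.05}, dt_h=0.02)
        init = ReactorState(
            0.0, {"aerobe": 0.5, "anaerobe": 0.1}, {"glc_e": 4.0, "dex_e": 0.0}, cfg.s_star
        )
        traj = simulate(toy_models, dead, cfg, init, 10.0)
        D = cfg.dilution_rate
        for sp_name, x0 in (("aerobe", 0.5), ("anaerobe", 0.1)):
            expected = x0 * np.exp(-D * traj.times)
            np.testing.assert_allclose(traj.biomass[sp_name], expected, rtol=1e-9)
        glc = traj.metabolites["glc_e"]
        dex = traj.metabolites["dex_e"]
        assert np.all(np.diff(glc) <= 1e-12) and glc[-1] > 2.0  # decays toward 2
        assert np.all(np.diff(dex) >= -1e-12) and dex[-1] < 0.05  # rises toward 0.05

    def test_gate_forces_pure_washout(self, toy_models, kinetics):
        """An anaerobe alone under oxygen above the threshold never grows."""
        cfg = ReactorConfig(s_feed={"dex_e": DEXTRAN_FEED_MM})
        init = ReactorState(0.0, {"anaerobe": 0.1}, {"dex_e": DEXTRAN_FEED_MM}, cfg.s_star)
        traj = simulate({"anaerobe": toy_models["anaerobe"]}, kinetics, cfg, init, 10.0)
        expected = 0.1 * np.exp(-cfg.dilution_rate * traj.times)
        np.testing.assert_allclose(traj.biomass["anaerobe"], expected, rtol=1e-9)
        assert any(e[0] == "gate" for e in traj.events)
        # biomass is non-increasing throughout the gated interval
        assert np.all(np.diff(traj.biomass["anaerobe"]) <= 0)

    def test_chemostat_closed_form(self):
        """Single-species glucose-limited chemostat reaches the textbook
        steady state: S = K D/(mu_max - D), X = Y (S_feed - S)."""
        y = 0.09
        model = make_single_substrate_model(y)
        kin = KineticParams()
        kin.set("mono", "glc_e", 10.0, 0.5)
        cfg = ReactorConfig(s_feed={"glc_e": 25.0}, dt_h=0.01)
        init = ReactorState(0.0, {"mono": 1.0}, {"glc_e": 25.0}, cfg.s_star)
        # the minimal model omits O2 entirely, so it is not an anaerobe
        traj = simulate({"mono": model}, kin, cfg, init, 100.0, record_every=20,
                        gated_species=set())
        D = cfg.dilution_rate
        mu_max = y * 10.0
        S_expected = 0.5 * D / (mu_max - D)
        X_expected = y * (25.0 - S_expected)
        final = traj.final_state
        assert final.metabolites["glc_e"] == pytest.approx(S_expected, rel=0.01)
        assert final.biomass["mono"] == pytest.approx(X_expected, rel=0.01)

    def test_step_size_convergence(self, toy_models, kinetics):
        """Halving dt changes the 50-h steady-state biomasses by < 0.5%."""
        feeds = {"glc_e": 5.0, "dex_e": DEXTRAN_FEED_MM}
        finals = {}
        for dt in (0.01, 0.005):
            cfg = ReactorConfig(s_feed=feeds, dt_h=dt)
            init = default_initial_state(cfg)
            traj = simulate(toy_models, kinetics, cfg, init, 50.0, record_every=100)
            finals[dt] = traj.final_state
        for sp_name in toy_models:
            a = finals[0.01].biomass[sp_name]
            b = finals[0.005].biomass[sp_name]
            assert abs(a - b) / max(a, b) < 0.005

    def test_two_species_states_and_carbon_audit(self, toy_models, kinetics):
        """High glucose feeds the aerobe-anaerobe state with O2 below the
        gate; low glucose leaves the aerobe alone.  Carbon in >= carbon out
        at steady state."""
        cfg_hi = ReactorConfig(s_feed={"glc_e": 5.0, "dex_e": DEXTRAN_FEED_MM})
        init = default_initial_state(cfg_hi)
        hi = simulate(toy_models, kinetics, cfg_hi, init, 50.0, record_every=50)
        final_hi = hi.final_state
        assert final_hi.biomass["anaerobe"] > 0.01
        assert final_hi.oxygen < cfg_hi.o2_threshold_mM
        audit = hi.carbon_audit(toy_models)
        assert audit["carbon_in"] >= audit["carbon_out"] > 0

        cfg_lo = cfg_hi.with_feed("glc_e", 1.0)
        lo = simulate(toy_models, kinetics, cfg_lo, default_initial_state(cfg_lo), 50.0, record_every=50)
        final_lo = lo.final_state
        assert final_lo.biomass["anaerobe"] < 1e-3
        assert final_lo.oxygen > cfg_lo.o2_threshold_mM

    def test_clamp_events_logged_without_exhaustion_cap(self, toy_models, kinetics):
        """With the availability cap disabled, a coarse step overdraws the
        residual glucose pool; the state is floored at zero and each clamp
        is logged."""
        cfg = ReactorConfig(
            s_feed={"glc_e": 0.5, "dex_e": 0.0},
            exhaustion_cap=False, dt_h=0.05, oxygen_mode="explicit",
        )
        init = ReactorState(0.0, {"aerobe": 0.5}, {"glc_e": 0.2, "dex_e": 0.0}, cfg.s_star)
        traj = simulate({"aerobe": toy_models["aerobe"]}, kinetics, cfg, init, 10.0)
        assert any(e[0] == "clamp" and e[2] == "glc_e" for e in traj.events)
        assert np.all(traj.metabolites["glc_e"] >= 0.0)

    def test_duration_shorter_than_step_rejected(self, toy_models, kinetics, reactor_config):
        init = default_initial_state(reactor_config)
        with pytest.raises(ValueError):
            simulate(toy_models, kinetics, reactor_config, init, 0.001)
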