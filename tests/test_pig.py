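"""Tests for the virtual-pig physiology: mass balance, dilution, ventilation,
maneuver response and measurement noise."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeoloop.pig import (
    SOLUTES,
    PigParams,
    SimulationFault,
    VentilatorSettings,
    concentration,
    etco2_reading,
    initial_state,
    sample_bga,
    simulate_vna_trace,
    step_physiology,
)
from homeoloop.volume import VnaConfig, compute_vna_delta, maneuver_timeline

NO_INFUSION = {"g20": 0.0, "cacl": 0.0, "bicarb": 0.0, "bes": 0.0, "bes2": 0.0}


def ablated_params(**overrides) -> PigParams:
    """Kinetics switched off: no production, elimination or losses."""
    zero = {s: 0.0 for s in SOLUTES}
    kwargs = dict(
        production=zero, elimination=zero, loss_rate=0.0, vco2_osc_amplitude=0.0
    )
    kwargs.update(overrides)
    return PigParams(**kwargs)


VENT = VentilatorSettings()


class TestMassAndVolumeBalance:
    def test_ablated_zero_infusion_state_is_a_fixed_point(self):
        params = ablated_params()
        state = initial_state(params)
        for _ in range(50):
            new = step_physiology(state, params, NO_INFUSION, VENT, dt=7.0)
            assert new.amounts == state.amounts
            assert new.blood_volume == state.blood_volume
            state = new

    def test_g20_infusion_adds_glucose_mass(self):
        # 10 ml/h for 60 min carries 10 ml x 1.111 mmol/ml
        params = ablated_params()
        state = initial_state(params)
        before = state.amounts["glucose"]
        infusions = dict(NO_INFUSION, g20=10.0)
        for _ in range(60):
            state = step_physiology(state, params, infusions, VENT, dt=1.0)
        assert state.amounts["glucose"] - before == pytest.approx(11.11, abs=0.01)

    def test_solute_free_volume_dilutes_every_concentration(self):
        # BES2-only infusion of dV: every concentration x V/(V+dV)
        params = ablated_params()
        state = initial_state(params)
        before = {s: concentration(state, params, s) for s in ("glucose", "calcium")}
        v0 = state.blood_volume
        state = step_physiology(state, params, dict(NO_INFUSION, bes2=600.0), VENT, dt=30.0)
        dv = state.blood_volume - v0
        assert dv == pytest.approx(300.0)
        for s in ("glucose", "calcium"):
            assert concentration(state, params, s) == pytest.approx(
                before[s] * v0 / (v0 + dv)
            )

    @given(
        st.lists(
            st.tuples(st.floats(0, 50), st.floats(0, 50), st.floats(0, 300)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=25)
    def test_mass_and_volume_conservation_over_any_infusion_sequence(self, sequence):
        """With kinetics ablated, amounts and volume track the integrals of
        the infusions to machine precision."""
        params = ablated_params()
        state = initial_state(params)
        expected_glucose = state.amounts["glucose"]
        expected_volume = state.blood_volume
        for g20, cacl, bes2 in sequence:
            state = step_physiology(
                state, params, dict(NO_INFUSION, g20=g20, cacl=cacl, bes2=bes2), VENT
            )
            expected_glucose += g20 / 60.0 * 1.111
            expected_volume += (g20 + cacl + bes2) / 60.0
        assert state.amounts["glucose"] == pytest.approx(expected_glucose, rel=1e-12)
        assert state.blood_volume == pytest.approx(expected_volume, rel=1e-12)

    def test_nonpositive_volume_aborts_with_diagnostic(self):
        params = ablated_params(loss_rate=100.0)
        state = initial_state(params)
        with pytest.raises(SimulationFault, match="volume"):
            for _ in range(100):
                state = step_physiology(state, params, NO_INFUSION, VENT, dt=10.0)


class TestVentilation:
    def test_doubling_respiratory_rate_halves_etco2(self):
        params = ablated_params()
        state = initial_state(params)
        slow = step_physiology(
            state, params, NO_INFUSION, dataclasses.replace(VENT, respiratory_rate=10.0)
        )
        fast = step_physiology(
            state, params, NO_INFUSION, dataclasses.replace(VENT, respiratory_rate=20.0)
        )
        assert fast.etco2 == pytest.approx(slow.etco2 / 2.0)

    def test_alveolar_formula_magnitude(self):
        # 0.863 * 200 / (12 * 0.370 L) ~ 38.9 mmHg: physiological
        params = ablated_params()
        state = step_physiology(initial_state(params), params, NO_INFUSION, VENT)
        assert state.etco2 == pytest.approx(0.863 * 200.0 / (12.0 * 0.370), rel=1e-9)

    def test_dead_space_reduces_effective_ventilation(self):
        params = ablated_params()
        more_dead_space = ablated_params(dead_space=250.0)
        a = step_physiology(initial_state(params), params, NO_INFUSION, VENT)
        b = step_physiology(initial_state(more_dead_space), more_dead_space, NO_INFUSION, VENT)
        assert b.etco2 > a.etco2


class TestVnaResponse:
    TIMELINE = maneuver_timeline(VnaConfig(), pip=20.0, baseline_peep=5.0)

    def test_no_deficit_gives_baseline_delta(self):
        params = ablated_params(vna_noise_sd=0.0)
        state = initial_state(params)  # blood volume at the lateral target
        trace = simulate_vna_trace(state, params, self.TIMELINE)
        assert compute_vna_delta(trace) == pytest.approx(params.vna_baseline)

    def test_delta_is_linear_in_deficit(self):
        params = ablated_params(vna_noise_sd=0.0, vna_baseline=5.0, vna_volume_gain=0.02)
        state = dataclasses.replace(
            initial_state(params), blood_volume=params.blood_volume - 500.0
        )
        trace = simulate_vna_trace(state, params, self.TIMELINE)
        assert compute_vna_delta(trace) == pytest.approx(5.0 + 0.02 * 500.0)  # = 15

    def test_dorsal_position_needs_more_volume(self):
        params = ablated_params(vna_noise_sd=0.0)
        state = initial_state(params)
        lateral = compute_vna_delta(simulate_vna_trace(state, params, self.TIMELINE))
        dorsal_state = dataclasses.replace(state, position="back")
        dorsal = compute_vna_delta(simulate_vna_trace(dorsal_state, params, self.TIMELINE))
        assert dorsal > lateral
        assert dorsal - lateral == pytest.approx(
            params.vna_volume_gain * params.position_volume_stress["back"]
        )

    def test_trace_dips_during_hold_and_recovers(self):
        params = ablated_params(vna_noise_sd=0.0)
        state = initial_state(params)
        trace = simulate_vna_trace(state, params, self.TIMELINE)
        pressures = dict(trace)
        assert pressures[0.0] == state.systolic_bp  # no dip before the hold
        assert min(pressures.values()) == pressures[20.0]  # nadir at end of hold
        assert pressures[80.0] == pytest.approx(state.systolic_bp)  # recovered


class TestMeasurement:
    def test_noise_free_sample_equals_state(self):
        params = ablated_params(noise_sd={k: 0.0 for k in PigParams().noise_sd})
        state = initial_state(params)
        sample = sample_bga(state, params, np.random.default_rng(0))
        assert sample.glucose == concentration(state, params, "glucose")
        assert sample.ionized_calcium == concentration(state, params, "calcium")
        assert sample.abe == concentration(state, params, "buffer_base")
        assert etco2_reading(state, params) == state.etco2

    def test_fixed_seed_replays_identical_samples(self):
        params = PigParams()
        state = initial_state(params)
        a = [sample_bga(state, params, np.random.default_rng(42)) for _ in range(1)]
        b = [sample_bga(state, params, np.random.default_rng(42)) for _ in range(1)]
        assert a == b

    def test_sample_variance_matches_configured_sd(self):
        """Monte-Carlo: variance of 10^4 noisy glucose samples within 5% of
        the configured SD^2."""
        params = PigParams()
        state = initial_state(params)
        rng = np.random.default_rng(2024)
        draws = np.array([sample_bga(state, params, rng).glucose for _ in range(10_000)])
        assert draws.var() == pytest.approx(params.noise_sd["glucose"] ** 2, rel=0.05)
        assert draws.mean() == pytest.approx(5.5, abs=0.01)
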