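"""Model equations, equilibria, and integrator accuracy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzneuro.ap import detect_spikes
from thzneuro.model import (ConductanceModulation, HHParams, NeuronState,
                            StimulusProtocol, THzField, conductance_scaling,
                            gating_rates, h_inf, hh_derivatives,
                            resting_state, simulate, simulate_batch,
                            thz_field_waveform)


class TestGatingRates:
    def test_h_steady_state_is_half_at_minus_60(self):
        assert h_inf(-60.0) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("v", [-100.0, -50.0, 0.0, 50.0])
    @pytest.mark.parametrize("which", ["m", "h", "n"])
    def test_rates_nonnegative(self, v, which):
        alpha, beta = gating_rates(v, which)
        assert alpha >= 0 and beta >= 0

    def test_n_gate_rates_match_arithmetic_oracle(self):
        # independent transcription of the squid-axon n-gate rate formulas
        v = -55.0
        x = v + 55.0
        alpha_oracle = 0.01 * 10.0 if x == 0 else \
            0.01 * x / (1.0 - math.exp(-x / 10.0))
        beta_oracle = 0.125 * math.exp(-(v + 65.0) / 80.0)
        alpha, beta = gating_rates(v, "n")
        assert alpha == pytest.approx(alpha_oracle, rel=1e-12)
        assert beta == pytest.approx(beta_oracle, rel=1e-12)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError, match="gate"):
            gating_rates(-60.0, "q")


class TestDerivatives:
    def test_unit_interval_is_forward_invariant_at_edges(self):
        p = HHParams()
        mod = ConductanceModulation()
        lo = NeuronState(v=-50.0, m=0.0, h=0.0, n=0.0)
        hi = NeuronState(v=-50.0, m=1.0, h=1.0, n=1.0)
        d_lo = hh_derivatives(lo, p, mod, 0.0)
        d_hi = hh_derivatives(hi, p, mod, 0.0)
        assert d_lo.m >= 0 and d_lo.n >= 0 and d_lo.h >= 0
        assert d_hi.m <= 0 and d_hi.n <= 0 and d_hi.h <= 0

    def test_resting_fixed_point_has_zero_derivatives(self, default_rest):
        d = hh_derivatives(default_rest, HHParams(), ConductanceModulation(),
                           0.0)
        assert abs(d.v) < 1e-9
        assert abs(d.m) < 1e-9 and abs(d.h) < 1e-9 and abs(d.n) < 1e-9

    def test_voltage_derivative_matches_manual_current_sum(self):
        # hand-computed membrane currents for the default (n^1, gated leak)
        p = HHParams()
        state = NeuronState(v=-50.0, m=0.2, h=0.6, n=0.3)
        i_na = 120.0 * 0.2 ** 3 * 0.6 * (-50.0 - 50.0)
        i_k = 36.0 * 0.3 * (-50.0 + 77.0)
        i_leak = 0.3 * 0.3 * (-50.0 + 54.4)
        expected = (5.0 - i_na - i_k - i_leak) / 0.75
        d = hh_derivatives(state, p, ConductanceModulation(), 5.0)
        assert d.v == pytest.approx(expected, rel=1e-12)

    def test_gate_exponent_and_leak_variants_change_currents(self):
        state = NeuronState(v=-50.0, m=0.2, h=0.6, n=0.3)
        mod = ConductanceModulation()
        base = hh_derivatives(state, HHParams(), mod, 0.0).v
        n4 = hh_derivatives(state, HHParams(k_gate_exponent=4), mod, 0.0).v
        ohmic = hh_derivatives(state, HHParams(leak_gated=False), mod, 0.0).v
        # n^4 < n for n in (0,1): less K current, so dv/dt is larger
        assert n4 > base
        assert ohmic != base


class TestConductanceScaling:
    def test_no_field_is_identity(self):
        assert conductance_scaling(ConductanceModulation()) == (1.0, 1.0)

    @given(st.floats(min_value=0.0, max_value=10.0),
           st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling_is_linear_in_intensity(self, intensity, beta_K):
        s1, _ = conductance_scaling(
            ConductanceModulation(beta_K=beta_K, intensity=intensity))
        s2, _ = conductance_scaling(
            ConductanceModulation(beta_K=beta_K, intensity=2 * intensity))
        assert s2 - 1.0 == pytest.approx(2.0 * (s1 - 1.0), abs=1e-9)

    def test_sodium_unchanged_by_default(self):
        for intensity in (0.0, 1.0, 7.5):
            _, sNa = conductance_scaling(
                ConductanceModulation(beta_K=0.4, intensity=intensity))
            assert sNa == 1.0

    def test_negative_scale_factor_rejected(self):
        with pytest.raises(ValueError):
            ConductanceModulation(beta_K=-2.0, intensity=1.0)


class TestTHzField:
    def test_waveform_at_zero_and_half_period(self):
        fld = THzField(A=2.5, nu=36.0)
        assert thz_field_waveform(fld, 0.0) == pytest.approx(2.5)
        half_period = 1.0 / (2.0 * 36.0e12)
        assert thz_field_waveform(fld, half_period) == pytest.approx(-2.5)

    def test_angular_frequency(self):
        assert THzField(A=1.0, nu=36.0).omega == pytest.approx(
            2.0 * math.pi * 36.0e12)

    def test_polarization_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            THzField(A=1.0, nu=36.0, u=(0.0, 0.0, 2.0))


class TestSimulate:
    def test_rest_is_persistent_without_stimulus(self, rest_trace,
                                                 default_rest):
        assert np.max(np.abs(rest_trace.v - default_rest.v)) < 1.0

    def test_trace_length_and_determinism(self, tonic_params):
        mod = ConductanceModulation()
        proto = StimulusProtocol.constant(5.0, 50.0)
        a = simulate(tonic_params, mod, proto, 50.0, 0.01)
        b = simulate(tonic_params, mod, proto, 50.0, 0.01)
        assert len(a) == 5001
        np.testing.assert_array_equal(a.v, b.v)

    def test_gating_variables_stay_in_unit_interval(self, tonic_trace):
        for arr in (tonic_trace.m, tonic_trace.h, tonic_trace.n):
            assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_potassium_scaling_suppresses_spiking(self, tonic_params):
        proto = StimulusProtocol.constant(10.0, 300.0)
        n_spikes = {}
        for sK in (1.0, 1.5):
            mod = ConductanceModulation.from_scale(sK)
            tr = simulate(tonic_params, mod, proto, 300.0, 0.01)
            n_spikes[sK] = len(detect_spikes(tr))
        assert n_spikes[1.5] < n_spikes[1.0]

    def test_step_halving_spike_time_agreement(self, tonic_params):
        proto = StimulusProtocol.constant(10.0, 200.0)
        times = {}
        for dt in (0.01, 0.005):
            tr = simulate(tonic_params, ConductanceModulation(), proto,
                          200.0, dt)
            times[dt] = [s.peak_time for s in detect_spikes(tr)]
        assert len(times[0.01]) == len(times[0.005]) > 3
        assert np.max(np.abs(np.array(times[0.01])
                             - np.array(times[0.005]))) < 0.05

    def test_adaptive_reference_agrees_with_rk4(self, tonic_params):
        proto = StimulusProtocol.constant(10.0, 60.0)
        rk4 = simulate(tonic_params, ConductanceModulation(), proto, 60.0,
                       0.01)
        ref = simulate(tonic_params, ConductanceModulation(), proto, 60.0,
                       0.01, method="adaptive")
        t_rk4 = [s.peak_time for s in detect_spikes(rk4)]
        t_ref = [s.peak_time for s in detect_spikes(ref)]
        assert len(t_rk4) == len(t_ref) > 0
        assert np.max(np.abs(np.array(t_rk4) - np.array(t_ref))) < 0.05

    def test_batch_matches_individual_runs(self, tonic_params):
        proto = StimulusProtocol.constant(10.0, 100.0)
        sKs = [1.0, 1.3]
        batch = simulate_batch(tonic_params, sKs, proto, 100.0, 0.01)
        for i, sK in enumerate(sKs):
            single = simulate(tonic_params, ConductanceModulation.from_scale(sK),
                              proto, 100.0, 0.01)
            np.testing.assert_allclose(batch[i], single.v, atol=1e-9)


class TestRestingState:
    @pytest.mark.parametrize("k_exp,gated", [(1, True), (1, False),
                                             (4, True), (4, False)])
    def test_rest_is_hyperpolarized_and_internally_consistent(self, k_exp,
                                                              gated):
        p = HHParams(k_gate_exponent=k_exp, leak_gated=gated)
        st_ = resting_state(p)
        assert -80.0 < st_.v < -55.0
        d = hh_derivatives(st_, p, ConductanceModulation(), 0.0)
        assert abs(d.v) < 1e-6

    def test_scaling_moves_rest_toward_potassium_reversal(self):
        p = HHParams()
        v_plain = resting_state(p).v
        v_scaled = resting_state(p, ConductanceModulation.from_scale(1.5)).v
        assert v_scaled < v_plain
        assert v_scaled > p.vK


class TestInvariantValidation:
    def test_gating_bounds_enforced(self):
        with pytest.raises(ValueError):
            NeuronState(v=-60.0, m=1.2, h=0.5, n=0.5)

    def test_reversal_ordering_enforced(self):
        with pytest.raises(ValueError):
            HHParams(vK=-50.0, vL=-60.0)

    def test_overlapping_stimulus_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusProtocol(segments=((0.0, 100.0, 5.0), (50.0, 100.0, 5.0)))
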