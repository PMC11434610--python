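"""Spike detection and action-potential metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzneuro.ap import (APConventions, ap_features, detect_spikes, fi_curve,
                         firing_rate, phase_plot, rheobase_search, rmp,
                         steady_state_rate)
from thzneuro.errors import BracketError
from thzneuro.model import (ConductanceModulation, HHParams, NeuronState,
                            StimulusProtocol, VoltageTrace, resting_state,
                            simulate)

RMP_CONV = APConventions(baseline="rmp")


def gaussian_bump_trace(peaks_ms, sigma_ms=0.5, dt=0.01, T=100.0,
                        baseline=-70.0, peak_v=20.0):
    t = np.arange(0.0, T, dt)
    v = np.full_like(t, baseline)
    for p in peaks_ms:
        v += (peak_v - baseline) * np.exp(-0.5 * ((t - p) / sigma_ms) ** 2)
    return VoltageTrace(dt=dt, v=v)


class TestDetectSpikes:
    def test_flat_trace_has_no_events(self):
        tr = VoltageTrace(dt=0.01, v=np.full(1000, -70.0))
        assert detect_spikes(tr) == []

    def test_three_bumps_three_events(self):
        tr = gaussian_bump_trace([20.0, 50.0, 80.0])
        events = detect_spikes(tr)
        assert len(events) == 3
        for e, expected in zip(events, [20.0, 50.0, 80.0]):
            assert e.peak_time == pytest.approx(expected, abs=0.05)

    def test_count_matches_crossing_scan_oracle(self, tonic_trace):
        events = detect_spikes(tonic_trace)
        v = tonic_trace.v
        oracle = int(np.sum((v[:-1] < 0.0) & (v[1:] >= 0.0)))
        assert len(events) == oracle > 5

    def test_idempotent_under_subthreshold_padding(self, tonic_trace):
        events = detect_spikes(tonic_trace)
        padded = VoltageTrace(dt=tonic_trace.dt, v=np.concatenate(
            [tonic_trace.v, np.full(5000, -70.0)]))
        events_padded = detect_spikes(padded)
        assert [e.peak_time for e in events] == \
            [e.peak_time for e in events_padded]

    def test_event_invariants(self, tonic_trace):
        for e in detect_spikes(tonic_trace):
            assert e.threshold_time <= e.peak_time
            assert e.threshold_v < e.peak_v


class TestAPFeatures:
    def test_triangular_pulse_half_width_is_half_base(self):
        dt = 0.01
        base_w = 4.0  # ms
        t = np.arange(0.0, 20.0, dt)
        v = np.full_like(t, -70.0)
        ramp = 1.0 - np.abs(t - 10.0) / (base_w / 2.0)
        v += 90.0 * np.clip(ramp, 0.0, None)
        tr = VoltageTrace(dt=dt, v=v)
        spike = detect_spikes(tr)[0]
        feats = ap_features(tr, spike, RMP_CONV, baseline_v=-70.0)
        assert feats.fwhm == pytest.approx(base_w / 2.0, abs=2 * dt)

    def test_gaussian_fwhm_closed_form(self):
        sigma = 0.4
        tr = gaussian_bump_trace([30.0], sigma_ms=sigma, T=60.0)
        spike = detect_spikes(tr)[0]
        feats = ap_features(tr, spike, RMP_CONV, baseline_v=-70.0)
        assert feats.fwhm == pytest.approx(
            2.0 * sigma * np.sqrt(2.0 * np.log(2.0)), abs=tr.dt)

    @given(st.floats(min_value=-30.0, max_value=30.0),
           st.integers(min_value=1, max_value=4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_width_invariant_to_shift_and_linear_in_dilation(self, shift,
                                                             dilation):
        tr = gaussian_bump_trace([30.0], sigma_ms=0.5, T=60.0)
        spike = detect_spikes(tr)[0]
        w0 = ap_features(tr, spike, RMP_CONV, baseline_v=-70.0).fwhm

        shifted = VoltageTrace(dt=tr.dt, v=tr.v + shift)
        s2 = detect_spikes(shifted, peak_threshold=shift)[0]
        w_shift = ap_features(shifted, s2, RMP_CONV,
                              baseline_v=-70.0 + shift).fwhm
        assert w_shift == pytest.approx(w0, rel=1e-6)

        dilated = VoltageTrace(dt=tr.dt * dilation, v=tr.v)
        s3 = detect_spikes(dilated)[0]
        w_dil = ap_features(dilated, s3, RMP_CONV, baseline_v=-70.0).fwhm
        assert w_dil == pytest.approx(w0 * dilation, rel=1e-6)

    def test_model_ap_narrows_under_potassium_scaling(self, tonic_params):
        proto = StimulusProtocol.constant(10.0, 300.0)
        widths = {}
        for sK in (1.0, 1.2):
            tr = simulate(tonic_params, ConductanceModulation.from_scale(sK),
                          proto, 300.0, 0.01)
            spike = detect_spikes(tr)[0]
            widths[sK] = ap_features(tr, spike).fwhm
        assert widths[1.2] / widths[1.0] < 1.0


class TestFiringRate:
    def test_count_over_window(self):
        times = np.linspace(50.0, 950.0, 10)
        assert firing_rate(times, (0.0, 1000.0)) == pytest.approx(10.0)

    def test_empty_train_is_zero(self):
        assert firing_rate([], (0.0, 1000.0)) == 0.0

    def test_poisson_rate_recovery(self, rng):
        # 20 Hz over 100 s; counting error bounded by 3 sigma of Poisson
        times = np.sort(rng.uniform(0.0, 100_000.0, 2000))
        est = firing_rate(times, (0.0, 100_000.0))
        assert abs(est - 20.0) <= 3.0 * np.sqrt(2000.0) / 100.0


class TestRMP:
    def test_constant_trace(self):
        tr = VoltageTrace(dt=0.1, v=np.full(500, -70.0))
        assert rmp(tr, (0.0, 40.0)) == pytest.approx(-70.0)

    def test_matches_fixed_point_oracle(self, rest_trace, default_rest):
        assert rmp(rest_trace, (100.0, 200.0)) == pytest.approx(
            default_rest.v, abs=0.1)

    def test_scaling_hyperpolarizes_rmp(self):
        p = HHParams()
        values = {}
        for sK in (1.0, 1.5):
            mod = ConductanceModulation.from_scale(sK)
            tr = simulate(p, mod, StimulusProtocol.none(), 100.0, 0.01)
            values[sK] = rmp(tr, (50.0, 100.0))
        assert values[1.5] < values[1.0]

    def test_window_outside_trace_rejected(self):
        tr = VoltageTrace(dt=0.1, v=np.full(100, -70.0))
        with pytest.raises(ValueError):
            rmp(tr, (0.0, 500.0))


class TestRheobase:
    def test_bisection_matches_grid_search(self, tonic_params):
        res = 0.05
        mod = ConductanceModulation()
        rb = rheobase_search(tonic_params, mod, amp_range=(0.0, 5.0),
                             resolution=res)
        # exhaustive scan at the same resolution
        state0 = resting_state(tonic_params, mod)
        grid = np.arange(0.0, 5.0 + res, res)
        fired = []
        for amp in grid:
            tr = simulate(tonic_params, mod,
                          StimulusProtocol.constant(amp, 30.0), 50.0, 0.01,
                          initial_state=state0)
            fired.append(len(detect_spikes(tr)) > 0)
        grid_rheo = grid[np.argmax(fired)]
        assert abs(rb - grid_rheo) <= res

    def test_scaling_raises_rheobase(self, tonic_params):
        rb1 = rheobase_search(tonic_params, ConductanceModulation(),
                              amp_range=(0.0, 20.0))
        rb2 = rheobase_search(tonic_params,
                              ConductanceModulation.from_scale(1.5),
                              amp_range=(0.0, 20.0))
        assert rb2 > rb1 > 0.0

    def test_bad_bracket_raises(self, tonic_params):
        with pytest.raises(BracketError):
            rheobase_search(tonic_params, ConductanceModulation(),
                            amp_range=(0.0, 1e-4))


class TestFICurve:
    def test_subthreshold_amplitudes_give_zero_counts(self, tonic_params):
        curve = fi_curve(tonic_params, ConductanceModulation(),
                         [0.1, 0.3, 0.5], duration=100.0)
        assert np.all(curve.counts == 0)

    def test_points_match_independent_runs(self, tonic_params):
        amps = [4.0, 8.0]
        curve = fi_curve(tonic_params, ConductanceModulation(), amps,
                         duration=200.0)
        state0 = resting_state(tonic_params, ConductanceModulation())
        for amp, count in zip(amps, curve.counts):
            tr = simulate(tonic_params, ConductanceModulation(),
                          StimulusProtocol.constant(amp, 200.0), 200.0, 0.01,
                          initial_state=state0)
            assert count == len(detect_spikes(tr))

    def test_scaled_curve_lies_at_or_below_control(self, tonic_params):
        amps = np.linspace(3.0, 6.0, 4)
        ctrl = fi_curve(tonic_params, ConductanceModulation(), amps,
                        duration=200.0)
        scaled = fi_curve(tonic_params, ConductanceModulation.from_scale(1.5),
                          amps, duration=200.0)
        assert np.all(scaled.counts <= ctrl.counts)


class TestPhasePlot:
    def test_linear_ramp_constant_slope(self):
        dt = 0.1
        v = -70.0 + 2.0 * np.arange(0.0, 10.0, dt)
        _, dvdt = phase_plot(VoltageTrace(dt=dt, v=v))
        np.testing.assert_allclose(dvdt, 2.0, rtol=1e-9)

    def test_central_vs_forward_difference(self, tonic_trace):
        v_mid, dvdt = phase_plot(tonic_trace)
        fwd = np.diff(tonic_trace.v) / tonic_trace.dt
        # central vs forward difference differ by O(dt * |v''|)
        assert np.max(np.abs(dvdt - fwd[:-1])) < 0.6 * tonic_trace.dt * \
            np.max(np.abs(np.diff(fwd))) / tonic_trace.dt + 1e-6
        assert len(v_mid) == len(tonic_trace) - 2
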