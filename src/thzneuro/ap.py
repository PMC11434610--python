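"""Action-potential detection and waveform metrics.

Covers the standard current-clamp measurements: spike detection, AP
threshold / amplitude / width, resting membrane potential, rheobase
(30 ms pulse by default), F-I (input-output) curves and phase plots.

Conventions (all configurable through :class:`APConventions`):

* AP threshold -- first sample on the upstroke where dv/dt >= 20 mV/ms;
* spike peak -- local maximum above 0 mV, peaks separated by >= 2 ms;
* width baseline -- midpoint between threshold voltage and peak voltage
  (``baseline="threshold"``), or between a resting baseline and peak
  (``baseline="rmp"``); the full width at half maximum (FWHM) and the
  "half-width" of an AP are the same computation under one convention;
* steady-state firing -- spikes counted after discarding the first 100 ms
  of a constant-stimulus run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BracketError, MetricUndefinedError
from .model import (ConductanceModulation, HHParams, NeuronState,
                    StimulusProtocol, VoltageTrace, resting_state, simulate)

__all__ = [
    "SpikeEvent",
    "APFeatures",
    "APConventions",
    "FICurve",
    "detect_spikes",
    "ap_features",
    "firing_rate",
    "rmp",
    "rheobase_search",
    "fi_curve",
    "phase_plot",
]


@dataclass(frozen=True)
class SpikeEvent:
    """A detected action potential.

    ``peak_time`` is refined by parabolic interpolation around the peak
    sample, so it is continuous rather than grid-quantized; ``peak_index``
    is the integer sample of the maximum.
    """

    peak_time: float
    peak_v: float
    threshold_time: float
    threshold_v: float
    peak_index: int

    def __post_init__(self):
        if self.threshold_time > self.peak_time:
            raise ValueError("threshold_time must not exceed peak_time")
        if self.threshold_v >= self.peak_v:
            raise ValueError("threshold_v must be below peak_v")


@dataclass
class APFeatures:
    """Per-trace / per-AP metric bundle; unset metrics are None."""

    fwhm: float | None = None
    half_width: float | None = None
    amplitude: float | None = None
    threshold: float | None = None
    rmp: float | None = None
    rheobase: float | None = None
    firing_rate: float | None = None


@dataclass(frozen=True)
class APConventions:
    """Measurement conventions for AP metrics (see module docstring)."""

    dvdt_threshold: float = 20.0      # mV/ms criterion for AP threshold
    peak_threshold: float = 0.0       # mV; crossings below this are ignored
    min_interval: float = 2.0         # ms between accepted peaks
    baseline: str = "threshold"       # "threshold" | "rmp"
    steady_state_discard: float = 100.0  # ms discarded for steady-state rate

    def __post_init__(self):
        if self.baseline not in ("threshold", "rmp"):
            raise ValueError("baseline must be 'threshold' or 'rmp'")


def _parabolic_peak(v: np.ndarray, j: int, dt: float) -> tuple[float, float]:
    """Refine peak time/value at sample ``j`` by a 3-point parabola."""
    if 0 < j < v.size - 1:
        y0, y1, y2 = v[j - 1], v[j], v[j + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                return (j + delta) * dt, y1 - 0.25 * (y0 - y2) * delta
    return j * dt, v[j]


def detect_spikes(trace: VoltageTrace, peak_threshold: float = 0.0,
                  min_interval: float = 2.0,
                  dvdt_threshold: float = 20.0) -> list[SpikeEvent]:
    """Detect APs as upward crossings of ``peak_threshold`` followed by a peak.

    Returns one :class:`SpikeEvent` per accepted peak, in time order; peaks
    closer than ``min_interval`` ms to the previous accepted peak are
    discarded.  Subthreshold traces yield an empty list.
    """
    if min_interval < trace.dt:
        raise ValueError("min_interval must be at least one sample interval")
    v = trace.v
    dt = trace.dt
    up = np.where((v[:-1] < peak_threshold) & (v[1:] >= peak_threshold))[0]
    dvdt = np.diff(v) / dt
    events: list[SpikeEvent] = []
    last_peak_t = -np.inf
    for c in up:
        j = c + 1
        while j + 1 < v.size and v[j + 1] >= v[j]:
            j += 1
        peak_t, peak_v = _parabolic_peak(v, j, dt)
        if peak_t - last_peak_t < min_interval:
            continue
        # threshold: walk back from the crossing over the fast upstroke
        k = c
        while k > 0 and dvdt[k - 1] >= dvdt_threshold:
            k -= 1
        thr_v = v[k]
        if thr_v >= peak_v:  # degenerate plateau; skip
            continue
        events.append(SpikeEvent(peak_time=peak_t, peak_v=float(peak_v),
                                 threshold_time=k * dt, threshold_v=float(thr_v),
                                 peak_index=int(j)))
        last_peak_t = peak_t
    return events


def _width_at_level(v: np.ndarray, dt: float, peak_index: int,
                    level: float) -> float:
    """Duration around ``peak_index`` during which v >= level, interpolated."""
    if v[peak_index] <= level:
        raise MetricUndefinedError(
            "peak does not rise above the half-amplitude level")
    a = peak_index
    while a > 0 and v[a - 1] >= level:
        a -= 1
    b = peak_index
    while b + 1 < v.size and v[b + 1] >= level:
        b += 1
    t_left = a * dt
    if a > 0:
        t_left = (a - 1 + (v[a - 1] - level) / (v[a - 1] - v[a])) * dt
    t_right = b * dt
    if b + 1 < v.size:
        t_right = (b + (v[b] - level) / (v[b] - v[b + 1])) * dt
    return t_right - t_left


def ap_features(trace: VoltageTrace, spike: SpikeEvent,
                conventions: APConventions = APConventions(),
                baseline_v: float | None = None) -> APFeatures:
    """Single-AP metrics for one detected spike.

    ``baseline_v`` supplies the resting baseline for the ``"rmp"`` width
    convention; it defaults to the first sample of the trace.  Width is the
    (interpolated) duration spent above the midpoint between baseline and
    peak; ``fwhm`` and ``half_width`` carry the same value.
    """
    if conventions.baseline == "threshold":
        base = spike.threshold_v
    else:
        base = baseline_v if baseline_v is not None else float(trace.v[0])
    if spike.peak_v <= base:
        raise MetricUndefinedError("AP peak is not above the width baseline")
    level = 0.5 * (base + spike.peak_v)
    width = _width_at_level(trace.v, trace.dt, spike.peak_index, level)
    return APFeatures(fwhm=width, half_width=width,
                      amplitude=spike.peak_v - spike.threshold_v,
                      threshold=spike.threshold_v)


def firing_rate(spike_times, window: tuple[float, float]) -> float:
    """Mean firing rate in Hz: spikes inside ``window`` (ms) / window length."""
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    times = np.asarray(list(spike_times), dtype=float)
    count = int(np.sum((times >= start) & (times < end))) if times.size else 0
    return count / ((end - start) / 1000.0)


def steady_state_rate(trace: VoltageTrace,
                      conventions: APConventions = APConventions()) -> float:
    """Firing rate after discarding the initial transient of a constant run."""
    spikes = detect_spikes(trace, conventions.peak_threshold,
                           conventions.min_interval,
                           conventions.dvdt_threshold)
    t_end = (len(trace) - 1) * trace.dt
    return firing_rate([s.peak_time for s in spikes],
                       (conventions.steady_state_discard, t_end))


def rmp(trace: VoltageTrace, window: tuple[float, float]) -> float:
    """Resting membrane potential: mean voltage over a pre-stimulus window (ms)."""
    start, end = window
    t_end = (len(trace) - 1) * trace.dt
    if not (0.0 <= start < end <= t_end + trace.dt / 2):
        raise ValueError("RMP window lies outside the trace")
    i0 = int(round(start / trace.dt))
    i1 = int(round(end / trace.dt)) + 1
    return float(np.mean(trace.v[i0:i1]))


def _elicits_spike(params: HHParams, mod: ConductanceModulation,
                   amplitude: float, pulse_duration: float, dt: float,
                   initial_state: NeuronState,
                   conventions: APConventions) -> bool:
    # pad past the pulse so spikes triggered at pulse offset are counted
    T = pulse_duration + 20.0
    tr = simulate(params, mod, StimulusProtocol.constant(amplitude, pulse_duration),
                  T, dt, initial_state=initial_state)
    return len(detect_spikes(tr, conventions.peak_threshold,
                             conventions.min_interval,
                             conventions.dvdt_threshold)) > 0


def rheobase_search(params: HHParams, mod: ConductanceModulation,
                    pulse_duration: float = 30.0,
                    amp_range: tuple[float, float] = (0.0, 50.0),
                    resolution: float = 0.01, dt: float = 0.01,
                    conventions: APConventions = APConventions()) -> float:
    """Minimal constant-pulse amplitude eliciting at least one spike.

    Bisects ``amp_range`` down to ``resolution`` (uA/cm^2).  Raises
    :class:`BracketError` when the bracket does not contain the threshold
    (the upper bound fails to fire, or the lower bound already fires).
    """
    lo, hi = amp_range
    if hi <= lo:
        raise ValueError("amp_range must satisfy lo < hi")
    state0 = resting_state(params, mod)
    if not _elicits_spike(params, mod, hi, pulse_duration, dt, state0, conventions):
        raise BracketError(f"upper bracket {hi} uA/cm^2 elicits no spike")
    if lo > 0 and _elicits_spike(params, mod, lo, pulse_duration, dt, state0,
                                 conventions):
        raise BracketError(f"lower bracket {lo} uA/cm^2 is already suprathreshold")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _elicits_spike(params, mod, mid, pulse_duration, dt, state0, conventions):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class FICurve:
    """Input-output curve: spike count at each step amplitude."""

    amplitudes: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.amplitudes) <= 0):
            raise ValueError("amplitudes must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")


def fi_curve(params: HHParams, mod: ConductanceModulation, amplitudes,
             duration: float = 500.0, dt: float = 0.01,
             conventions: APConventions = APConventions()) -> FICurve:
    """Spike count per constant-current step, each from a fresh simulation."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    state0 = resting_state(params, mod)
    counts = []
    for amp in amplitudes:
        tr = simulate(params, mod, StimulusProtocol.constant(amp, duration),
                      duration, dt, initial_state=state0)
        counts.append(len(detect_spikes(tr, conventions.peak_threshold,
                                        conventions.min_interval,
                                        conventions.dvdt_threshold)))
    return FICurve(amplitudes=amplitudes, counts=np.array(counts))


def phase_plot(trace: VoltageTrace) -> tuple[np.ndarray, np.ndarray]:
    """(v, dv/dt) pairs with central-difference dv/dt; length = len - 2."""
    if len(trace) < 3:
        raise ValueError("phase plot needs at least 3 samples")
    v = trace.v
    dvdt = (v[2:] - v[:-2]) / (2.0 * trace.dt)
    return v[1:-1].copy(), dvdt
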