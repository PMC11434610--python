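"""Voltage-clamp step protocols, synthetic channel currents, and curve fits.

Three step protocols are built in, mirroring standard Nav / Kv / K-leak
characterization:

* ``nav``   -- hold -100 mV (20 ms), test pulses -80 ... -10 mV;
* ``kv``    -- hold -100 mV, test pulses -70 ... +130 mV (100 ms);
* ``kleak`` -- hold -70 mV, test pulses -120 ... -30 mV (400 ms), with only
  steps at or above -65 mV entering the leak analysis.

Channel currents are generated from first-order gate kinetics with
Boltzmann voltage dependence: under a clamp the command potential is
piecewise constant, so each gate relaxes exponentially toward its steady
state and the current has a closed form.  This doubles as the synthetic
trace generator backend (a single channel type per trace set; the
pharmacological isolation used experimentally is represented by that
restriction, not modelled).

Analysis: I-V extraction (peak or steady-state), Boltzmann fits of
activation/inactivation curves, single-exponential tau fits, and the
ohmic leak fit restricted to depolarized steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError

__all__ = [
    "StepProtocol",
    "CurrentTraceSet",
    "BoltzmannGate",
    "GatedChannel",
    "LeakChannel",
    "nav_channel",
    "kv_channel",
    "BoltzmannFit",
    "IVData",
    "LeakFit",
    "make_protocol",
    "run_voltage_clamp",
    "iv_curve",
    "fit_boltzmann",
    "fit_exponential",
    "leak_analysis",
]


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepProtocol:
    """A family of voltage steps from a common holding potential."""

    holding_v: float
    pre_duration: float
    step_levels: tuple
    step_duration: float
    inter_sweep: float = 0.0

    def __post_init__(self):
        levels = tuple(float(v) for v in self.step_levels)
        object.__setattr__(self, "step_levels", levels)
        if self.pre_duration <= 0 or self.step_duration <= 0:
            raise ValueError("durations must be positive")
        if len(levels) >= 2 and np.any(np.diff(levels) <= 0):
            raise ValueError("step_levels must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.step_levels)


_PRESETS = {
    # holding, pre ms, (lo, hi) mV, step duration ms
    "nav": (-100.0, 20.0, (-80.0, -10.0), 25.0),
    "kv": (-100.0, 20.0, (-70.0, 130.0), 100.0),
    "kleak": (-70.0, 20.0, (-120.0, -30.0), 400.0),
}


def make_protocol(preset: str, step_increment: float = 10.0) -> StepProtocol:
    """Build one of the three printed step protocols.

    ``step_increment`` must evenly divide the preset's voltage range.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of "
                         f"{sorted(_PRESETS)}")
    holding, pre, (lo, hi), dur = _PRESETS[preset]
    n_inc = (hi - lo) / step_increment
    if abs(n_inc - round(n_inc)) > 1e-9:
        raise ValueError(
            f"step_increment {step_increment} does not divide the "
            f"{preset} range {lo}..{hi} mV")
    levels = lo + step_increment * np.arange(int(round(n_inc)) + 1)
    return StepProtocol(holding_v=holding, pre_duration=pre,
                        step_levels=tuple(levels), step_duration=dur)


@dataclass
class CurrentTraceSet:
    """Per-step clamp current traces (one row per step level)."""

    protocol: StepProtocol
    currents: np.ndarray  # shape (n_steps, n_samples)
    dt: float
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.shape[0] != self.protocol.n_steps:
            raise ValueError("one current trace per step level required")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def step_onset_index(self) -> int:
        return int(round(self.protocol.pre_duration / self.dt))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.currents.shape[1]) * self.dt

    def step_segment(self, i: int) -> np.ndarray:
        """The samples of trace ``i`` during the voltage step."""
        return self.currents[i, self.step_onset_index:]


# ---------------------------------------------------------------------------
# channel models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoltzmannGate:
    """First-order gate with sigmoidal steady state and fixed time constant.

    ``direction`` 'activation' opens with depolarization, 'inactivation'
    closes with depolarization.  ``tau`` is in ms.
    """

    v_half: float
    k: float
    tau: float
    direction: str = "activation"

    def __post_init__(self):
        if self.k <= 0 or self.tau <= 0:
            raise ValueError("slope k and tau must be positive")
        if self.direction not in ("activation", "inactivation"):
            raise ValueError("direction must be activation or inactivation")

    def steady(self, v):
        v = np.asarray(v, dtype=float)
        if self.direction == "activation":
            return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))
        return 1.0 / (1.0 + np.exp((v - self.v_half) / self.k))

    def relax(self, v_from, v_to, t):
        """Gate value at times ``t`` after stepping from ``v_from`` to ``v_to``."""
        y0 = self.steady(v_from)
        yinf = self.steady(v_to)
        return yinf + (y0 - yinf) * np.exp(-np.asarray(t, dtype=float) / self.tau)


@dataclass(frozen=True)
class GatedChannel:
    """Conductance g_max * prod(gate^exponent) * (V - e_rev)."""

    g_max: float
    e_rev: float
    gates: tuple  # of (BoltzmannGate, int exponent)

    def current(self, v_hold: float, v_step: float, t) -> np.ndarray:
        open_frac = np.ones_like(np.asarray(t, dtype=float))
        for gate, p in self.gates:
            open_frac = open_frac * gate.relax(v_hold, v_step, t) ** p
        return self.g_max * open_frac * (v_step - self.e_rev)

    def steady_current(self, v) -> np.ndarray:
        open_frac = 1.0
        for gate, p in self.gates:
            open_frac = open_frac * gate.steady(v) ** p
        return self.g_max * open_frac * (np.asarray(v, dtype=float) - self.e_rev)


@dataclass(frozen=True)
class LeakChannel:
    """Ohmic, voltage-independent conductance."""

    g: float
    e_rev: float

    def current(self, v_hold: float, v_step: float, t) -> np.ndarray:
        return np.full_like(np.asarray(t, dtype=float),
                            self.g * (v_step - self.e_rev))

    def steady_current(self, v) -> np.ndarray:
        return self.g * (np.asarray(v, dtype=float) - self.e_rev)


def nav_channel(g_max: float = 120.0, e_rev: float = 60.0,
                act: BoltzmannGate | None = None,
                inact: BoltzmannGate | None = None) -> GatedChannel:
    """Transient Na+ channel, m^3 h kinetics."""
    act = act or BoltzmannGate(v_half=-30.0, k=6.0, tau=0.3)
    inact = inact or BoltzmannGate(v_half=-60.0, k=6.2, tau=2.0,
                                   direction="inactivation")
    return GatedChannel(g_max=g_max, e_rev=e_rev,
                        gates=((act, 3), (inact, 1)))


def kv_channel(g_max: float = 36.0, e_rev: float = -77.0,
               v_half: float = -10.0, k: float = 14.0, tau: float = 4.0,
               n_exponent: int = 1) -> GatedChannel:
    """Delayed-rectifier K+ channel, n^p kinetics."""
    gate = BoltzmannGate(v_half=v_half, k=k, tau=tau)
    return GatedChannel(g_max=g_max, e_rev=e_rev, gates=((gate, n_exponent),))


def run_voltage_clamp(channel, protocol: StepProtocol, dt: float = 0.1,
                      noise_sigma: float = 0.0,
                      seed: int | None = None) -> CurrentTraceSet:
    """Simulate the clamp currents of one channel under a step protocol.

    During the pre period the gates sit at their holding steady state; at
    step onset each gate relaxes exponentially toward the step steady
    state.  Gaussian noise of standard deviation ``noise_sigma`` is added
    pointwise (deterministic per ``seed``).
    """
    n_pre = int(round(protocol.pre_duration / dt))
    n_step = int(round(protocol.step_duration / dt))
    t_step = np.arange(n_step + 1) * dt
    rng = np.random.default_rng(seed)
    rows = []
    for level in protocol.step_levels:
        pre = np.full(n_pre, float(channel.steady_current(protocol.holding_v)))
        step = channel.current(protocol.holding_v, level, t_step)
        rows.append(np.concatenate([pre, step]))
    currents = np.asarray(rows)
    if noise_sigma > 0:
        currents = currents + rng.normal(0.0, noise_sigma, currents.shape)
    return CurrentTraceSet(protocol=protocol, currents=currents, dt=dt,
                           noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# I-V extraction and fits
# ---------------------------------------------------------------------------

@dataclass
class IVData:
    """Current-voltage pairs, one per step level."""

    v: np.ndarray
    i: np.ndarray
    mode: str

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.v.shape != self.i.shape:
            raise ValueError("v and i must have matching shapes")

    def slope(self) -> float:
        """Least-squares linear slope of the I-V points (conductance)."""
        return float(np.polyfit(self.v, self.i, 1)[0])


def iv_curve(traces: CurrentTraceSet, mode: str = "steady-state",
             window: tuple[float, float] | None = None) -> IVData:
    """Extract one current value per step.

    ``window`` is (start, end) in ms relative to step onset; defaults to
    the full step for ``peak`` and the last 20% for ``steady-state``.
    ``peak`` takes the signed extremum (largest |I|), ``steady-state`` the
    mean over the window.
    """
    if mode not in ("peak", "steady-state"):
        raise ValueError("mode must be 'peak' or 'steady-state'")
    dur = traces.protocol.step_duration
    if window is None:
        window = (0.0, dur) if mode == "peak" else (0.8 * dur, dur)
    start, end = window
    if not (0.0 <= start < end <= dur + traces.dt / 2):
        raise ValueError("window lies outside the voltage step")
    i0 = traces.step_onset_index + int(round(start / traces.dt))
    i1 = traces.step_onset_index + int(round(end / traces.dt)) + 1
    values = []
    for row in traces.currents:
        seg = row[i0:i1]
        if mode == "peak":
            values.append(seg[np.argmax(np.abs(seg))])
        else:
            values.append(np.mean(seg))
    return IVData(v=np.array(traces.protocol.step_levels),
                  i=np.array(values), mode=mode)


def conductance_from_iv(iv: IVData, e_rev: float) -> np.ndarray:
    """Chord conductance G = I / (V - E_rev) per step."""
    dv = iv.v - e_rev
    if np.any(np.abs(dv) < 1e-9):
        raise ValueError("a step level coincides with the reversal potential")
    return iv.i / dv


@dataclass
class BoltzmannFit:
    """Fitted sigmoid f(V) = g_max / (1 + exp(+-(v_half - V)/k))."""

    v_half: float
    slope_k: float
    g_max: float
    direction: str
    residual_norm: float
    tau: float | None = None

    def __post_init__(self):
        if self.slope_k <= 0:
            raise ValueError("fitted slope k must be positive")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        sign = 1.0 if self.direction == "activation" else -1.0
        return self.g_max / (1.0 + np.exp(sign * (self.v_half - v) / self.slope_k))

    def normalized(self, v):
        return self(v) / self.g_max


def fit_boltzmann(v, y, direction: str = "activation") -> BoltzmannFit:
    """Least-squares Boltzmann fit of (V, response) points.

    ``y`` may be raw conductances or currents already divided by driving
    force; the fitted amplitude ``g_max`` absorbs the scale, and
    normalization should use the fitted amplitude rather than the largest
    data point.  Requires at least 4 points spanning the transition.
    """
    if direction not in ("activation", "inactivation"):
        raise ValueError("direction must be activation or inactivation")
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.size < 4:
        raise InsufficientDataError("Boltzmann fit needs at least 4 points")
    sign = 1.0 if direction == "activation" else -1.0

    def f(vv, v_half, k, g_max):
        return g_max / (1.0 + np.exp(sign * (v_half - vv) / k))

    amp0 = float(np.max(np.abs(y))) or 1.0
    frac = y / (np.max(y) if np.max(y) != 0 else 1.0)
    # initial v_half: voltage whose response is nearest half-maximum
    v_half0 = float(v[np.argmin(np.abs(frac - 0.5))])
    k0 = (v.max() - v.min()) / 6.0
    try:
        popt, _ = curve_fit(f, v, y, p0=(v_half0, k0, amp0),
                            bounds=([v.min() - 100.0, 0.1, -np.inf],
                                    [v.max() + 100.0, 50.0, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}",
                       residuals=None) from exc
    resid = y - f(v, *popt)
    return BoltzmannFit(v_half=float(popt[0]), slope_k=float(popt[1]),
                        g_max=float(popt[2]), direction=direction,
                        residual_norm=float(np.linalg.norm(resid)))


def fit_exponential(t, y) -> tuple[float, float, float]:
    """Fit y(t) = y_inf + a * exp(-t / tau); returns (y_inf, a, tau).

    Used for the time-constant (tau) analysis of clamp trace segments.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("exponential fit needs at least 4 points")

    def f(tt, y_inf, a, tau):
        return y_inf + a * np.exp(-tt / tau)

    tau0 = max((t[-1] - t[0]) / 5.0, 1e-3)
    p0 = (float(y[-1]), float(y[0] - y[-1]), tau0)
    try:
        popt, _ = curve_fit(f, t, y, p0=p0, maxfev=20000,
                            bounds=([-np.inf, -np.inf, 1e-6],
                                    [np.inf, np.inf, np.inf]))
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


@dataclass
class LeakFit:
    """Ohmic leak fit over depolarized steps: I = g * (V - e_rev)."""

    g: float
    e_rev: float
    levels_used: tuple


def leak_analysis(traces: CurrentTraceSet, v_min: float = -65.0) -> LeakFit:
    """Linear leak fit restricted to steps at or above ``v_min`` mV.

    Uses the steady-state current of each qualifying step; the slope is the
    leak conductance and the voltage-axis intercept the reversal potential.
    """
    iv = iv_curve(traces, mode="steady-state")
    mask = iv.v >= v_min
    if int(mask.sum()) < 2:
        raise InsufficientDataError(
            f"need >= 2 steps at or above {v_min} mV; got {int(mask.sum())}")
    slope, intercept = np.polyfit(iv.v[mask], iv.i[mask], 1)
    if abs(slope) < 1e-15:
        raise FitError("leak slope is zero; reversal potential undefined")
    return LeakFit(g=float(slope), e_rev=float(-intercept / slope),
                   levels_used=tuple(float(v) for v in iv.v[mask]))
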