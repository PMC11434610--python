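"""Conductance-scaling sweep: how K+ enhancement suppresses firing.

This module runs the package's headline in-silico experiment.  The K+
conductance scale factor sK is swept over a grid (default 1.0 ... 3.0, step
0.01) under a constant suprathreshold current, for each of the four model
variants (K gate exponent 1 or 4, leak gated or ohmic).  For every sK it
measures

* the steady-state firing rate (spikes after the first 100 ms of a 500 ms
  run), and
* the FWHM of a single AP (the first detected AP of the run, which remains
  well defined even when tonic firing has ceased),

both as percentages of the unscaled (sK = 1) control, and then locates two
operating points by linear interpolation on the grid:

* the sK where the rate has fallen to 30% of control, reporting the FWHM
  percentage there, and
* the sK where the FWHM has fallen to 95% of control, reporting the rate
  reduction percentage there.

The default stimulus is 1.5x the tonic-firing threshold of the unscaled
control (found by bisection); variants with no tonic-firing regime are
reported as such rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ap import APConventions, ap_features, detect_spikes, firing_rate
from .errors import BracketError
from .model import (ConductanceModulation, HHParams, StimulusProtocol,
                    VoltageTrace, resting_state, simulate, simulate_batch)

__all__ = [
    "SweepResult",
    "VariantOutcome",
    "GridOutcome",
    "tonic_threshold",
    "conductance_sweep",
    "operating_points",
    "variant_grid_sweep",
]

VARIANTS = ((1, True), (1, False), (4, True), (4, False))


def tonic_threshold(params: HHParams, T: float = 500.0, dt: float = 0.01,
                    min_rate: float = 5.0, amp_max: float = 50.0,
                    tol: float = 1e-3,
                    conventions: APConventions = APConventions()) -> float:
    """Smallest constant current sustaining steady firing >= ``min_rate`` Hz.

    Bisection over [0, amp_max]; raises :class:`BracketError` when even
    ``amp_max`` does not sustain tonic firing (phasic variants).
    """
    mod = ConductanceModulation()
    state0 = resting_state(params, mod)

    def rate_at(amp: float) -> float:
        tr = simulate(params, mod, StimulusProtocol.constant(amp, T), T, dt,
                      initial_state=state0)
        spikes = detect_spikes(tr, conventions.peak_threshold,
                               conventions.min_interval,
                               conventions.dvdt_threshold)
        return firing_rate([s.peak_time for s in spikes],
                           (conventions.steady_state_discard, T))

    if rate_at(amp_max) < min_rate:
        raise BracketError(
            f"no tonic firing regime found below {amp_max} uA/cm^2")
    lo, hi = 0.0, amp_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rate_at(mid) >= min_rate:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class SweepResult:
    """Per-sK measurements of one variant sweep."""

    params: HHParams
    stim: float
    sK: np.ndarray
    rate_hz: np.ndarray
    fwhm_ms: np.ndarray

    @property
    def rate_pct(self) -> np.ndarray:
        return 100.0 * self.rate_hz / self.rate_hz[0]

    @property
    def fwhm_pct(self) -> np.ndarray:
        return 100.0 * self.fwhm_ms / self.fwhm_ms[0]


def _first_ap_fwhm(v: np.ndarray, dt: float,
                   conventions: APConventions) -> float:
    trace = VoltageTrace(dt=dt, v=v)
    spikes = detect_spikes(trace, conventions.peak_threshold,
                           conventions.min_interval, conventions.dvdt_threshold)
    if not spikes:
        return np.nan
    return ap_features(trace, spikes[0], conventions).fwhm


def conductance_sweep(params: HHParams, stim: float,
                      sK_grid=None, T: float = 500.0, dt: float = 0.01,
                      conventions: APConventions = APConventions()) -> SweepResult:
    """Run the sweep for one variant at a fixed constant stimulus."""
    if sK_grid is None:
        sK_grid = np.arange(1.0, 3.0001, 0.01)
    sK_grid = np.asarray(sK_grid, dtype=float)
    vb = simulate_batch(params, sK_grid, StimulusProtocol.constant(stim, T),
                        T, dt)
    i0 = int(conventions.steady_state_discard / dt)
    window_s = (vb.shape[1] - 1 - i0) * dt / 1000.0
    rates = np.empty(len(sK_grid))
    fwhms = np.empty(len(sK_grid))
    for i, row in enumerate(vb):
        trace = VoltageTrace(dt=dt, v=row)
        spikes = detect_spikes(trace, conventions.peak_threshold,
                               conventions.min_interval,
                               conventions.dvdt_threshold)
        n_ss = sum(s.peak_time >= conventions.steady_state_discard
                   for s in spikes)
        rates[i] = n_ss / window_s
        fwhms[i] = (ap_features(trace, spikes[0], conventions).fwhm
                    if spikes else np.nan)
    return SweepResult(params=params, stim=stim, sK=sK_grid,
                       rate_hz=rates, fwhm_ms=fwhms)


def _falling_crossing(x: np.ndarray, y: np.ndarray, level: float):
    """First downward crossing of ``level``; (x*, y-interp fraction, index)."""
    for i in range(len(y) - 1):
        yi, yj = y[i], y[i + 1]
        if not (np.isfinite(yi) and np.isfinite(yj)):
            continue
        if yi >= level and yj < level and yi != yj:
            f = (yi - level) / (yi - yj)
            return x[i] + f * (x[i + 1] - x[i]), i, f
    return None


def _interp(y: np.ndarray, i: int, f: float) -> float:
    return float(y[i] + f * (y[i + 1] - y[i]))


@dataclass
class VariantOutcome:
    """Operating points of one variant, or the reason it has none."""

    k_gate_exponent: int
    leak_gated: bool
    tonic: bool
    stim: float | None = None
    control_rate_hz: float | None = None
    control_fwhm_ms: float | None = None
    sK_at_rate30: float | None = None
    fwhm_pct_at_rate30: float | None = None
    sK_at_fwhm95: float | None = None
    rate_reduction_pct_at_fwhm95: float | None = None
    sweep: SweepResult | None = None

    def joint_error(self, fwhm_target: float = 95.0,
                    reduction_target: float = 70.0) -> float:
        """Largest absolute deviation (pp) from the two target values."""
        if not self.tonic or self.fwhm_pct_at_rate30 is None \
                or self.rate_reduction_pct_at_fwhm95 is None:
            return np.inf
        return max(abs(self.fwhm_pct_at_rate30 - fwhm_target),
                   abs(self.rate_reduction_pct_at_fwhm95 - reduction_target))


def operating_points(sweep: SweepResult) -> dict:
    """Locate the 30%-rate and 95%-FWHM operating points of a sweep."""
    out = {"sK_at_rate30": None, "fwhm_pct_at_rate30": None,
           "sK_at_fwhm95": None, "rate_reduction_pct_at_fwhm95": None}
    rate_pct = sweep.rate_pct
    fwhm_pct = sweep.fwhm_pct
    c30 = _falling_crossing(sweep.sK, rate_pct, 30.0)
    if c30 is not None:
        sk, i, f = c30
        out["sK_at_rate30"] = float(sk)
        out["fwhm_pct_at_rate30"] = _interp(fwhm_pct, i, f)
    c95 = _falling_crossing(sweep.sK, fwhm_pct, 95.0)
    if c95 is not None:
        sk, i, f = c95
        out["sK_at_fwhm95"] = float(sk)
        out["rate_reduction_pct_at_fwhm95"] = 100.0 - _interp(rate_pct, i, f)
    return out


@dataclass
class GridOutcome:
    """All four variant outcomes plus the best-matching one."""

    variants: list
    best: VariantOutcome | None
    joint_pass: bool
    tolerance_pp: float


def variant_grid_sweep(base_params: HHParams | None = None, sK_grid=None,
                       stim_factor: float = 1.5, T: float = 500.0,
                       dt: float = 0.01, tolerance_pp: float = 5.0,
                       conventions: APConventions = APConventions(),
                       keep_sweeps: bool = False) -> GridOutcome:
    """Sweep all four model variants and report the best-matching one.

    ``joint_pass`` is True when at least one variant realizes both operating
    points within ``tolerance_pp`` percentage points of (FWHM -> 95%,
    reduction -> 70%); otherwise the grid documents the mismatch.
    """
    base_params = base_params or HHParams()
    outcomes = []
    for k_exp, gated in VARIANTS:
        p = base_params.with_variant(k_exp, gated)
        try:
            thr = tonic_threshold(p, T=T, dt=dt, conventions=conventions)
        except BracketError:
            outcomes.append(VariantOutcome(k_gate_exponent=k_exp,
                                           leak_gated=gated, tonic=False))
            continue
        stim = stim_factor * thr
        sw = conductance_sweep(p, stim, sK_grid=sK_grid, T=T, dt=dt,
                               conventions=conventions)
        pts = operating_points(sw)
        outcomes.append(VariantOutcome(
            k_gate_exponent=k_exp, leak_gated=gated, tonic=True, stim=stim,
            control_rate_hz=float(sw.rate_hz[0]),
            control_fwhm_ms=float(sw.fwhm_ms[0]),
            sweep=sw if keep_sweeps else None, **pts))
    finite = [o for o in outcomes if np.isfinite(o.joint_error())]
    best = min(finite, key=lambda o: o.joint_error()) if finite else None
    joint_pass = best is not None and best.joint_error() <= tolerance_pp
    return GridOutcome(variants=outcomes, best=best, joint_pass=joint_pass,
                       tolerance_pp=tolerance_pp)
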