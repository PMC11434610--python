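"""Synthetic-data generators for every analysis stage.

All generators are pure functions of (configuration, seed) and emit ground
truth alongside the data, so each downstream stage can be tested as
parameter or label recovery:

* :func:`gen_spike_train` -- Poisson spike trains with an absolute
  refractory (dead-time) period;
* :func:`gen_waveform` -- biphasic extracellular spike templates (negative
  Gaussian trough lobe followed by a smaller positive Gaussian peak lobe)
  with controllable trough-to-peak duration and trough half-width;
* :func:`gen_unit_population` -- a recorded-population emulation: PYR and
  INT units drawn from long / short trough-to-peak modes, each unit
  assigned an increased / decreased / unchanged post-stimulation rate
  change according to configured population fractions;
* :func:`gen_current_traces` -- voltage-clamp trace sets (delegates to
  :func:`thzneuro.clamp.run_voltage_clamp`).

Default population fractions follow the recorded PYR populations:
sham (decreased, increased, unchanged) = (63.4, 10.8, 25.8)% over 93 units,
nerve-injured ("SNI") = (61.8, 20.3, 17.9)% over 123 units.  Directions are
allocated by largest-remainder proportional assignment and then shuffled,
so a finite population realizes the configured fractions as closely as
integer counts allow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .clamp import (CurrentTraceSet, LeakChannel, kv_channel, make_protocol,
                    nav_channel, run_voltage_clamp)
from .units import UnitFeatures, UnitWaveform

__all__ = [
    "ClassParams",
    "PopulationConfig",
    "SyntheticUnit",
    "Population",
    "gen_spike_train",
    "gen_waveform",
    "gen_unit_population",
    "gen_current_traces",
    "CONDITION_FRACTIONS",
]

#: printed population fractions (decreased, increased, unchanged) for PYR
CONDITION_FRACTIONS = {
    "sham": (0.634, 0.108, 0.258),
    "SNI": (0.618, 0.203, 0.179),
}


@dataclass(frozen=True)
class ClassParams:
    """Waveform/rate parameter distributions of one cell class."""

    ttp_mode_us: float          # mean trough-to-peak
    ttp_sigma_us: float
    half_width_mean_us: float
    half_width_sigma_us: float
    rate_mean_hz: float
    rate_sigma_hz: float


PYR_DEFAULTS = ClassParams(ttp_mode_us=600.0, ttp_sigma_us=60.0,
                           half_width_mean_us=300.0, half_width_sigma_us=40.0,
                           rate_mean_hz=5.0, rate_sigma_hz=1.5)
INT_DEFAULTS = ClassParams(ttp_mode_us=250.0, ttp_sigma_us=60.0,
                           half_width_mean_us=150.0, half_width_sigma_us=25.0,
                           rate_mean_hz=10.0, rate_sigma_hz=3.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of a synthetic recorded population.

    ``fractions`` is (decreased, increased, unchanged); it defaults to the
    printed PYR fractions of the chosen condition and is applied to both
    classes (interneuron fractions are not separately documented).
    Post-stimulation rates of affected units are the pre rate times
    ``effect_decrease`` / ``effect_increase``.
    """

    n_pyr: int = 93
    n_int: int = 15
    condition: str = "sham"
    fractions: tuple | None = None
    pyr: ClassParams = PYR_DEFAULTS
    int_: ClassParams = INT_DEFAULTS
    effect_decrease: float = 0.5
    effect_increase: float = 1.5
    epoch_duration_s: float = 60.0
    refractory_ms: float = 2.0
    fs: float = 30000.0
    waveform_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITION_FRACTIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        fr = self.fractions or CONDITION_FRACTIONS[self.condition]
        fr = tuple(float(x) for x in fr)
        if any(x < 0 for x in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        object.__setattr__(self, "fractions", fr)
        if self.n_pyr < 0 or self.n_int < 0:
            raise ValueError("unit counts must be non-negative")


def gen_spike_train(rate_hz: float, duration_s: float,
                    refractory_ms: float = 2.0,
                    seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Poisson-with-dead-time spike train; times in ms, sorted.

    Inter-spike intervals are ``refractory + Exp(1/rate)``, so the expected
    count over ``duration_s`` is ``duration * rate / (1 + rate * refractory)``.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz == 0:
        return np.empty(0)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    duration_ms = duration_s * 1000.0
    mean_isi_ms = refractory_ms + 1000.0 / rate_hz
    n_draw = int(duration_ms / mean_isi_ms * 1.5) + 50
    times: list[np.ndarray] = []
    t_last = 0.0
    while True:
        isis = refractory_ms + rng.exponential(1000.0 / rate_hz, n_draw)
        chunk = t_last + np.cumsum(isis)
        times.append(chunk)
        t_last = chunk[-1]
        if t_last > duration_ms:
            break
    all_times = np.concatenate(times)
    return all_times[all_times < duration_ms]


def gen_waveform(trough_to_peak_us: float, half_width_us: float,
                 amplitude: float = 1.0, fs: float = 30000.0,
                 noise_sigma: float = 0.0,
                 seed: int | np.random.Generator | None = 0,
                 peak_ratio: float = 0.4) -> UnitWaveform:
    """Biphasic spike template: Gaussian trough lobe then smaller peak lobe.

    The trough lobe's std is set so its width at half depth equals
    ``half_width_us``; the positive lobe (relative amplitude
    ``peak_ratio``) peaks ``trough_to_peak_us`` later.  A noise-free
    template round-trips through ``waveform_features`` to within one
    sample interval.
    """
    if fs < 20000.0:
        raise ValueError("sampling rate must be at least 20 kHz")
    dt_us = 1e6 / fs
    if trough_to_peak_us < 2 * dt_us or half_width_us < 2 * dt_us:
        raise ValueError(
            "waveform parameters unresolvable at this sampling rate")
    sigma_t = half_width_us / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_p = 1.5 * sigma_t
    t0 = 4.0 * sigma_t
    total = t0 + trough_to_peak_us + 4.0 * sigma_p
    t = np.arange(0.0, total, dt_us)
    v = (-amplitude * np.exp(-0.5 * ((t - t0) / sigma_t) ** 2)
         + peak_ratio * amplitude
         * np.exp(-0.5 * ((t - t0 - trough_to_peak_us) / sigma_p) ** 2))
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma, v.shape)
    return UnitWaveform(samples=v, fs=fs)


@dataclass
class SyntheticUnit:
    """One generated unit with its ground truth."""

    unit_id: int
    cell_class: str           # "PYR" | "INT"
    direction: str            # "decreased" | "increased" | "unchanged"
    waveform: UnitWaveform
    pre_spikes_ms: np.ndarray
    post_spikes_ms: np.ndarray
    true_trough_to_peak_us: float
    true_half_width_us: float
    pre_rate_hz: float
    post_rate_hz: float

    def features(self) -> UnitFeatures:
        from .units import waveform_features
        return waveform_features(self.waveform, mean_rate=self.pre_rate_hz)


@dataclass
class Population:
    units: list
    config: PopulationConfig

    def __len__(self) -> int:
        return len(self.units)

    def direction_fractions(self, cell_class: str | None = None) -> dict:
        """Empirical (decreased, increased, unchanged) fractions."""
        pool = [u for u in self.units
                if cell_class is None or u.cell_class == cell_class]
        n = len(pool)
        if n == 0:
            return {"decreased": 0.0, "increased": 0.0, "unchanged": 0.0}
        return {d: sum(u.direction == d for u in pool) / n
                for d in ("decreased", "increased", "unchanged")}


def _allocate_directions(n: int, fractions: tuple,
                         rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of direction labels, shuffled."""
    names = ("decreased", "increased", "unchanged")
    raw = [f * n for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most-owed first
    for j in range(short):
        counts[order[j]] += 1
    labels = [name for name, c in zip(names, counts) for _ in range(c)]
    return [labels[i] for i in rng.permutation(n)]


def gen_unit_population(cfg: PopulationConfig) -> Population:
    """Generate waveforms, pre/post spike trains and ground-truth labels."""
    rng = np.random.default_rng(cfg.seed)
    units: list[SyntheticUnit] = []
    uid = 0
    for cls_name, n, par in (("PYR", cfg.n_pyr, cfg.pyr),
                             ("INT", cfg.n_int, cfg.int_)):
        directions = _allocate_directions(n, cfg.fractions, rng)
        for i in range(n):
            ttp = max(3e6 / cfg.fs,
                      rng.normal(par.ttp_mode_us, par.ttp_sigma_us))
            hw = max(3e6 / cfg.fs,
                     rng.normal(par.half_width_mean_us, par.half_width_sigma_us))
            base = max(0.5, rng.normal(par.rate_mean_hz, par.rate_sigma_hz))
            mult = {"decreased": cfg.effect_decrease,
                    "increased": cfg.effect_increase,
                    "unchanged": 1.0}[directions[i]]
            post = base * mult
            wf = gen_waveform(ttp, hw, fs=cfg.fs,
                              noise_sigma=cfg.waveform_noise_sigma, seed=rng)
            units.append(SyntheticUnit(
                unit_id=uid, cell_class=cls_name, direction=directions[i],
                waveform=wf,
                pre_spikes_ms=gen_spike_train(base, cfg.epoch_duration_s,
                                              cfg.refractory_ms, rng),
                post_spikes_ms=gen_spike_train(post, cfg.epoch_duration_s,
                                               cfg.refractory_ms, rng),
                true_trough_to_peak_us=float(ttp),
                true_half_width_us=float(hw),
                pre_rate_hz=float(base), post_rate_hz=float(post)))
            uid += 1
    return Population(units=units, config=cfg)


_DEFAULT_CHANNELS = {
    "nav": nav_channel,
    "kv": kv_channel,
    "kleak": lambda: LeakChannel(g=0.1, e_rev=-90.0),
}


def gen_current_traces(preset: str, channel=None, noise_sigma: float = 0.0,
                       seed: int | None = 0, step_increment: float = 10.0,
                       dt: float = 0.1) -> CurrentTraceSet:
    """Synthetic clamp trace set for one preset protocol.

    With ``channel=None`` a default single-channel model matching the
    preset is used (Nav m^3 h, Kv n-gate, or ohmic leak).  Delegates to
    :func:`thzneuro.clamp.run_voltage_clamp`; noise-free output is
    identical to a direct call.
    """
    protocol = make_protocol(preset, step_increment)
    if channel is None:
        try:
            channel = _DEFAULT_CHANNELS[preset]()
        except KeyError:
            raise ValueError(f"no default channel for preset {preset!r}")
    return run_voltage_clamp(channel, protocol, dt=dt,
                             noise_sigma=noise_sigma, seed=seed)
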