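"""Conductance-based cortical neuron model with THz-dependent K+ scaling.

The membrane equation is a modified Hodgkin-Huxley model,

    C dv/dt = I_stim - sNa*gNa*m^3*h*(v - vNa) - sK*gK*n^k*(v - vK) - I_leak

where ``sK`` and ``sNa`` are multiplicative conductance scale factors that
represent the effect of a high-frequency (tens of THz) optical field on the
channel proteins.  The field oscillates ~10 orders of magnitude faster than
the membrane time constant, so it never enters the equations as a drive;
only its time-averaged intensity does, through a linear conductance scaling
law (see :class:`ConductanceModulation`).

Two readings of the K+ current are supported and selectable through
:class:`HHParams`:

* ``k_gate_exponent`` -- the activation gate power ``k`` in ``n^k`` (1 or 4),
* ``leak_gated`` -- whether the leak term is ``gL*n*(v - vL)`` (gated) or the
  conventional ohmic ``gL*(v - vL)``.

The m/n rate functions follow the classic squid-axon formulation (optionally
voltage-shifted); the h gate relaxes toward a sigmoidal steady state
``h_inf(v) = 1/(1 + exp((v + 60)/6.2))`` with time constant
``1/(alpha_h + beta_h)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels
from .errors import BracketError, IntegrationError

__all__ = [
    "NeuronState",
    "HHParams",
    "THzField",
    "ConductanceModulation",
    "StimulusProtocol",
    "VoltageTrace",
    "gating_rates",
    "steady_state_gates",
    "hh_derivatives",
    "conductance_scaling",
    "thz_field_waveform",
    "resting_state",
    "simulate",
    "simulate_batch",
]

RATE_SETS = ("classic",)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NeuronState:
    """Instantaneous model state: membrane potential and gating variables.

    Attributes
    ----------
    v : float
        Membrane potential (mV).
    m, h, n : float
        Dimensionless gating variables in [0, 1]: Na+ activation (m),
        Na+ inactivation (h) and K+ activation (n).
    """

    v: float
    m: float
    h: float
    n: float

    def __post_init__(self):
        if not math.isfinite(self.v):
            raise ValueError("membrane potential must be finite")
        for name in ("m", "h", "n"):
            y = getattr(self, name)
            if not (0.0 <= y <= 1.0):
                raise ValueError(f"gating variable {name}={y} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.m, self.h, self.n])


@dataclass(frozen=True)
class HHParams:
    """Constants of the modified Hodgkin-Huxley membrane model.

    Units: capacitance uF/cm^2, conductances mS/cm^2, potentials mV.

    ``k_gate_exponent`` and ``leak_gated`` select the model variant (see
    module docstring).  ``v_shift`` shifts the m/n rate functions along the
    voltage axis (positive = depolarizing shift of the curves); the h-gate
    steady state is a fixed property of the model and is not shifted.
    """

    C: float = 0.75
    gNa_max: float = 120.0
    gK_max: float = 36.0
    gL: float = 0.3
    vNa: float = 50.0
    vK: float = -77.0
    vL: float = -54.4
    k_gate_exponent: int = 1
    leak_gated: bool = True
    rate_set: str = "classic"
    v_shift: float = 0.0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("membrane capacitance C must be positive")
        for name in ("gNa_max", "gK_max", "gL"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if not (self.vK < self.vL < self.vNa):
            raise ValueError("reversal potentials must satisfy vK < vL < vNa")
        if self.k_gate_exponent not in (1, 4):
            raise ValueError("k_gate_exponent must be 1 or 4")
        if self.rate_set not in RATE_SETS:
            raise ValueError(f"unknown rate_set {self.rate_set!r}")

    def with_variant(self, k_gate_exponent: int, leak_gated: bool) -> "HHParams":
        """Return a copy with a different (gate exponent, leak) variant."""
        return replace(self, k_gate_exponent=k_gate_exponent, leak_gated=leak_gated)


@dataclass(frozen=True)
class THzField:
    """A monochromatic THz field E(t) = A * u * cos(w*t + phi).

    Attributes
    ----------
    A : float
        Field amplitude (model units).
    nu : float
        Frequency in THz; the angular frequency is ``w = 2*pi*nu*1e12`` rad/s.
    phi : float
        Phase in radians.
    u : tuple
        Polarization unit vector.
    """

    A: float
    nu: float = 36.0
    phi: float = 0.0
    u: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("field frequency nu must be positive (THz)")
        norm = math.sqrt(sum(c * c for c in self.u))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("polarization vector u must have unit norm")

    @property
    def omega(self) -> float:
        """Angular frequency in rad/s."""
        return 2.0 * math.pi * self.nu * 1e12

    @property
    def mean_intensity(self) -> float:
        """Cycle-averaged intensity A^2/2 (model units)."""
        return 0.5 * self.A * self.A


def thz_field_waveform(fld: THzField, t):
    """Scalar field value along the polarization axis at time ``t`` (seconds)."""
    return fld.A * np.cos(fld.omega * np.asarray(t, dtype=float) + fld.phi)


@dataclass(frozen=True)
class ConductanceModulation:
    """Linear map from field intensity to conductance scale factors.

    The conductance of the K+ channel grows approximately linearly with the
    applied field intensity while the Na+ conductance is essentially
    unaffected, hence the defaults ``beta_Na = 0``:

        sK  = 1 + beta_K  * intensity
        sNa = 1 + beta_Na * intensity

    Intensity is in model-relative units; ``intensity = 0`` is the no-field
    control and yields the identity scaling.
    """

    beta_K: float = 0.0
    beta_Na: float = 0.0
    intensity: float = 0.0

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("field intensity must be non-negative")
        sK, sNa = self.scale_factors()
        if sK < 0 or sNa < 0:
            raise ValueError("conductance scale factors must be non-negative")

    def scale_factors(self) -> tuple[float, float]:
        return (1.0 + self.beta_K * self.intensity,
                1.0 + self.beta_Na * self.intensity)

    @classmethod
    def from_field(cls, fld: THzField, beta_K: float,
                   beta_Na: float = 0.0) -> "ConductanceModulation":
        """Build a modulation from a field's cycle-averaged intensity."""
        return cls(beta_K=beta_K, beta_Na=beta_Na, intensity=fld.mean_intensity)

    @classmethod
    def from_scale(cls, sK: float, sNa: float = 1.0) -> "ConductanceModulation":
        """Build a modulation that realizes given scale factors at intensity 1."""
        return cls(beta_K=sK - 1.0, beta_Na=sNa - 1.0, intensity=1.0)


def conductance_scaling(mod: ConductanceModulation) -> tuple[float, float]:
    """Return the (sK, sNa) conductance scale-factor pair."""
    return mod.scale_factors()


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant injected current I_stim(t).

    ``segments`` is an ordered list of (start_ms, duration_ms,
    amplitude_uA_per_cm2); outside all segments the stimulus is zero.
    """

    segments: tuple = ()

    def __post_init__(self):
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -math.inf
        for start, dur, _amp in sorted(segs):
            if dur < 0:
                raise ValueError("segment duration must be non-negative")
            if start < prev_end:
                raise ValueError("stimulus segments must not overlap")
            prev_end = start + dur

    @classmethod
    def constant(cls, amplitude: float, duration_ms: float,
                 start_ms: float = 0.0) -> "StimulusProtocol":
        return cls(segments=((start_ms, duration_ms, amplitude),))

    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls(segments=())

    def amplitude_at(self, t_ms):
        """Vectorized stimulus amplitude at time(s) ``t_ms``."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        for start, dur, amp in self.segments:
            out += np.where((t >= start) & (t < start + dur), amp, 0.0)
        return out


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential trace.

    ``v`` has shape (n_samples,); optional gating arrays share that shape.
    """

    dt: float
    v: np.ndarray
    m: np.ndarray | None = None
    h: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.dt <= 0:
            raise ValueError("sample interval dt must be positive")
        if self.v.size < 2:
            raise ValueError("a trace needs at least two samples")

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.v.size) * self.dt

    def __len__(self) -> int:
        return self.v.size


# ---------------------------------------------------------------------------
# rate functions and derivatives
# ---------------------------------------------------------------------------

def _vtrap(x, scale):
    """x / (1 - exp(-x/scale)), continuous through x = 0 (limit = scale)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / scale))
    return np.where(small, scale, out)


def _rates_m(u):
    alpha = 0.1 * _vtrap(u + 40.0, 10.0)
    beta = 4.0 * np.exp(-(u + 65.0) / 18.0)
    return alpha, beta


def _rates_n(u):
    alpha = 0.01 * _vtrap(u + 55.0, 10.0)
    beta = 0.125 * np.exp(-(u + 65.0) / 80.0)
    return alpha, beta


def _rates_h(u):
    alpha = 0.07 * np.exp(-(u + 65.0) / 20.0)
    beta = 1.0 / (1.0 + np.exp(-(u + 35.0) / 10.0))
    return alpha, beta


def h_inf(v):
    """Steady-state Na+ inactivation, 1 / (1 + exp((v + 60)/6.2))."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) + 60.0) / 6.2))


def gating_rates(v, which: str, params: HHParams | None = None):
    """Opening/closing rates (alpha, beta) in 1/ms for gate ``which``.

    For the h gate the returned classic (alpha_h, beta_h) only set the time
    constant ``tau_h = 1/(alpha_h + beta_h)``; the steady state actually used
    by the dynamics is the sigmoid :func:`h_inf`.
    """
    params = params or HHParams()
    u = np.asarray(v, dtype=float) - params.v_shift
    if which == "m":
        return _rates_m(u)
    if which == "n":
        return _rates_n(u)
    if which == "h":
        return _rates_h(u)
    raise ValueError(f"unknown gate id {which!r}; expected 'm', 'h' or 'n'")


def steady_state_gates(v, params: HHParams | None = None) -> tuple:
    """Steady-state (m_inf, h_inf, n_inf) at potential ``v``."""
    params = params or HHParams()
    am, bm = gating_rates(v, "m", params)
    an, bn = gating_rates(v, "n", params)
    return am / (am + bm), h_inf(v), an / (an + bn)


def _membrane_currents(v, m, h, n, p: HHParams, sK, sNa):
    """(I_Na, I_K, I_leak) in uA/cm^2, vectorized over the state arrays."""
    i_na = sNa * p.gNa_max * (m ** 3) * h * (v - p.vNa)
    nk = n if p.k_gate_exponent == 1 else n ** 4
    i_k = sK * p.gK_max * nk * (v - p.vK)
    i_l = p.gL * (n * (v - p.vL) if p.leak_gated else (v - p.vL))
    return i_na, i_k, i_l


def hh_derivatives(state: NeuronState, params: HHParams,
                   mod: ConductanceModulation, stim: float) -> NeuronState:
    """Time derivative of the model state (units mV/ms and 1/ms).

    Returned as a :class:`NeuronState`-shaped record whose fields hold the
    derivatives; gating-variable bounds are not enforced on derivatives.
    """
    sK, sNa = mod.scale_factors()
    dv, dm, dh, dn = _rhs(np.asarray(state.v), np.asarray(state.m),
                          np.asarray(state.h), np.asarray(state.n),
                          params, sK, sNa, stim)
    out = NeuronState.__new__(NeuronState)
    out.v, out.m, out.h, out.n = float(dv), float(dm), float(dh), float(dn)
    return out


def _rhs(v, m, h, n, p: HHParams, sK, sNa, stim):
    u = v - p.v_shift
    am, bm = _rates_m(u)
    an, bn = _rates_n(u)
    ah, bh = _rates_h(u)
    i_na, i_k, i_l = _membrane_currents(v, m, h, n, p, sK, sNa)
    dv = (stim - i_na - i_k - i_l) / p.C
    dm = am * (1.0 - m) - bm * m
    dn = an * (1.0 - n) - bn * n
    dh = (h_inf(v) - h) * (ah + bh)
    return dv, dm, dh, dn


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def _steady_current(v, p: HHParams, sK, sNa):
    """Net outward membrane current at voltage v with gates at steady state."""
    m, h, n = steady_state_gates(v, p)
    i_na, i_k, i_l = _membrane_currents(v, m, h, n, p, sK, sNa)
    return i_na + i_k + i_l


def _jacobian(state_vec, p: HHParams, sK, sNa, eps=1e-6):
    f0 = np.array(_rhs(*state_vec, p, sK, sNa, 0.0))
    J = np.empty((4, 4))
    for j in range(4):
        pert = state_vec.copy()
        pert[j] += eps
        J[:, j] = (np.array(_rhs(*pert, p, sK, sNa, 0.0)) - f0) / eps
    return J


def resting_state(params: HHParams,
                  mod: ConductanceModulation | None = None,
                  v_range: tuple[float, float] = (-95.0, -20.0)) -> NeuronState:
    """Resting fixed point of the model at zero injected current.

    Scans the steady-state I-V relation over ``v_range`` for zero crossings,
    refines each by root search, and returns the most hyperpolarized stable
    equilibrium (stability judged by the eigenvalues of the full 4x4
    Jacobian).  If no equilibrium is linearly stable the most hyperpolarized
    root is returned.
    """
    mod = mod or ConductanceModulation()
    sK, sNa = mod.scale_factors()
    grid = np.linspace(v_range[0], v_range[1], 301)
    f = np.array([_steady_current(v, params, sK, sNa) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(grid[i])
        elif f[i] * f[i + 1] < 0:
            roots.append(brentq(_steady_current, grid[i], grid[i + 1],
                                args=(params, sK, sNa), xtol=1e-10))
    if not roots:
        raise BracketError(
            f"no resting equilibrium found in v range {v_range}")
    roots = sorted(roots)
    for v0 in roots:
        m0, h0, n0 = steady_state_gates(v0, params)
        vec = np.array([v0, m0, h0, n0])
        eig = np.linalg.eigvals(_jacobian(vec, params, sK, sNa))
        if np.all(eig.real < 0):
            return NeuronState(v=float(v0), m=float(m0), h=float(h0), n=float(n0))
    v0 = roots[0]
    m0, h0, n0 = steady_state_gates(v0, params)
    return NeuronState(v=float(v0), m=float(m0), h=float(h0), n=float(n0))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _integrate_rk4(y0, params, sK, sNa, stim_half, n_steps, dt,
                   record_gating, check_every=200):
    """Fixed-step RK4 over ``n_steps``; batch-vectorized over trailing axis.

    ``y0`` is (4, B); ``sK``/``sNa`` are scalars or (B,); ``stim_half`` holds
    the stimulus at half-step resolution (2*n_steps + 1 values).  Gating
    variables are clipped to [0, 1] after every step to keep round-off from
    pushing them out of the invariant box.

    Dispatches to the compiled kernel when numba is available; the numpy
    fallback below implements the identical scheme.
    """
    if _kernels.HAVE_NUMBA:
        B = y0.shape[1]
        sK_arr = np.broadcast_to(np.asarray(sK, dtype=float), (B,))
        sNa_arr = np.broadcast_to(np.asarray(sNa, dtype=float), (B,))
        out_v, out_g, t_div = _kernels.rk4_kernel(
            np.ascontiguousarray(y0, dtype=float), params.C, params.gNa_max,
            params.gK_max, params.gL, params.vNa, params.vK, params.vL,
            params.k_gate_exponent == 4, params.leak_gated, params.v_shift,
            np.ascontiguousarray(sK_arr), np.ascontiguousarray(sNa_arr),
            np.ascontiguousarray(stim_half, dtype=float), n_steps, dt,
            record_gating)
        if t_div >= 0.0:
            raise IntegrationError(t_div)
        gates = (out_g[0], out_g[1], out_g[2]) if record_gating else None
        return out_v, gates
    return _integrate_rk4_numpy(y0, params, sK, sNa, stim_half, n_steps, dt,
                                record_gating, check_every)


def _integrate_rk4_numpy(y0, params, sK, sNa, stim_half, n_steps, dt,
                         record_gating, check_every=200):
    v, m, h, n = (np.array(y0[i], dtype=float, copy=True) for i in range(4))
    B = v.shape[0]
    out_v = np.empty((n_steps + 1, B))
    out_v[0] = v
    gates = None
    if record_gating:
        gates = tuple(np.empty((n_steps + 1, B)) for _ in range(3))
        gates[0][0], gates[1][0], gates[2][0] = m, h, n
    half = 0.5 * dt
    sixth = dt / 6.0
    for i in range(n_steps):
        s0 = stim_half[2 * i]
        s1 = stim_half[2 * i + 1]
        s2 = stim_half[2 * i + 2]
        k1 = _rhs(v, m, h, n, params, sK, sNa, s0)
        k2 = _rhs(v + half * k1[0], m + half * k1[1], h + half * k1[2],
                  n + half * k1[3], params, sK, sNa, s1)
        k3 = _rhs(v + half * k2[0], m + half * k2[1], h + half * k2[2],
                  n + half * k2[3], params, sK, sNa, s1)
        k4 = _rhs(v + dt * k3[0], m + dt * k3[1], h + dt * k3[2],
                  n + dt * k3[3], params, sK, sNa, s2)
        v = v + sixth * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        m = np.clip(m + sixth * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1]), 0.0, 1.0)
        h = np.clip(h + sixth * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2]), 0.0, 1.0)
        n = np.clip(n + sixth * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3]), 0.0, 1.0)
        out_v[i + 1] = v
        if record_gating:
            gates[0][i + 1], gates[1][i + 1], gates[2][i + 1] = m, h, n
        if (i + 1) % check_every == 0 and not np.all(np.isfinite(v)):
            raise IntegrationError((i + 1) * dt)
    if not np.all(np.isfinite(v)):
        raise IntegrationError(n_steps * dt)
    return out_v, gates


def simulate(params: HHParams, mod: ConductanceModulation,
             protocol: StimulusProtocol, T: float, dt: float = 0.01,
             method: str = "rk4", record_gating: bool = False,
             initial_state: NeuronState | None = None) -> VoltageTrace:
    """Integrate the model for ``T`` ms and return the sampled trace.

    ``method`` is ``"rk4"`` (fixed-step, default) or ``"adaptive"``
    (high-accuracy adaptive reference via ``scipy.integrate.solve_ivp``,
    intended for oracle comparisons).  The initial state defaults to the
    resting fixed point for the given parameters and modulation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least one step")
    state0 = initial_state or resting_state(params, mod)
    n_steps = int(math.floor(T / dt + 1e-9))
    sK, sNa = mod.scale_factors()
    if method == "rk4":
        t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
        stim_half = protocol.amplitude_at(t_half)
        y0 = state0.as_array()[:, None]
        out_v, gates = _integrate_rk4(y0, params, sK, sNa, stim_half,
                                      n_steps, dt, record_gating)
        kwargs = {}
        if record_gating:
            kwargs = dict(m=gates[0][:, 0], h=gates[1][:, 0], n=gates[2][:, 0])
        return VoltageTrace(dt=dt, v=out_v[:, 0], **kwargs)
    if method == "adaptive":
        def fun(t, y):
            stim = float(protocol.amplitude_at(t))
            return np.array(_rhs(y[0], y[1], y[2], y[3], params, sK, sNa, stim))

        t_eval = np.arange(n_steps + 1) * dt
        sol = solve_ivp(fun, (0.0, n_steps * dt), state0.as_array(),
                        t_eval=t_eval, method="RK45", rtol=1e-9, atol=1e-11,
                        max_step=1.0)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(float(sol.t[-1]))
        kwargs = {}
        if record_gating:
            kwargs = dict(m=sol.y[1], h=sol.y[2], n=sol.y[3])
        return VoltageTrace(dt=dt, v=sol.y[0], **kwargs)
    raise ValueError(f"unknown integrator {method!r}")


def simulate_batch(params: HHParams, sK: Sequence[float],
                   protocol: StimulusProtocol, T: float, dt: float = 0.01,
                   sNa: Sequence[float] | float = 1.0,
                   initial_states: Sequence[NeuronState] | None = None) -> np.ndarray:
    """Integrate one model under many conductance scale factors at once.

    Returns an array of shape (len(sK), n_samples) of membrane potentials.
    Each batch member starts from its own resting fixed point (the resting
    potential depends on sK) unless ``initial_states`` is given.  This is the
    fast path for conductance sweeps; results are identical to per-member
    :func:`simulate` calls.
    """
    sK = np.asarray(sK, dtype=float)
    sNa_arr = np.broadcast_to(np.asarray(sNa, dtype=float), sK.shape).copy()
    if initial_states is None:
        initial_states = [
            resting_state(params, ConductanceModulation.from_scale(k, s))
            for k, s in zip(sK, sNa_arr)
        ]
    y0 = np.stack([st.as_array() for st in initial_states], axis=1)
    n_steps = int(math.floor(T / dt + 1e-9))
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    stim_half = protocol.amplitude_at(t_half)
    out_v, _ = _integrate_rk4(y0, params, sK, sNa_arr, stim_half, n_steps, dt,
                              record_gating=False)
    return out_v.T
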