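"""Compiled fixed-step RK4 kernel for the membrane model.

The kernel is a scalar-arithmetic transcription of ``model._rhs`` /
``model._integrate_rk4`` that numba can compile; when numba is unavailable
the package falls back to the vectorized numpy integrator, which computes
the same scheme.  Returns the divergence time (ms) as a float, -1.0 when the
run stayed finite, so the caller can raise a proper exception.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _vtrap_s(x: float, scale: float) -> float:
    if abs(x) < 1e-7:
        return scale
    return x / (1.0 - math.exp(-x / scale))


@njit(cache=True)
def _rhs_s(v, m, h, n, C, gNa, gK, gL, vNa, vK, vL,
           k4, leak_gated, vshift, sK, sNa, stim):
    u = v - vshift
    am = 0.1 * _vtrap_s(u + 40.0, 10.0)
    bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
    an = 0.01 * _vtrap_s(u + 55.0, 10.0)
    bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
    ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    hinf = 1.0 / (1.0 + math.exp((v + 60.0) / 6.2))
    i_na = sNa * gNa * m * m * m * h * (v - vNa)
    nk = n * n * n * n if k4 else n
    i_k = sK * gK * nk * (v - vK)
    i_l = gL * (n * (v - vL)) if leak_gated else gL * (v - vL)
    dv = (stim - i_na - i_k - i_l) / C
    dm = am * (1.0 - m) - bm * m
    dh = (hinf - h) * (ah + bh)
    dn = an * (1.0 - n) - bn * n
    return dv, dm, dh, dn


@njit(cache=True)
def rk4_kernel(y0, C, gNa, gK, gL, vNa, vK, vL, k4, leak_gated, vshift,
               sK, sNa, stim_half, n_steps, dt, record_gating):
    B = y0.shape[1]
    out_v = np.empty((n_steps + 1, B))
    if record_gating:
        out_g = np.empty((3, n_steps + 1, B))
    else:
        out_g = np.empty((3, 1, 1))
    half = 0.5 * dt
    sixth = dt / 6.0
    t_diverge = -1.0
    for b in range(B):
        v = y0[0, b]
        m = y0[1, b]
        h = y0[2, b]
        n = y0[3, b]
        sk = sK[b]
        sn = sNa[b]
        out_v[0, b] = v
        if record_gating:
            out_g[0, 0, b] = m
            out_g[1, 0, b] = h
            out_g[2, 0, b] = n
        for i in range(n_steps):
            s0 = stim_half[2 * i]
            s1 = stim_half[2 * i + 1]
            s2 = stim_half[2 * i + 2]
            dv1, dm1, dh1, dn1 = _rhs_s(v, m, h, n, C, gNa, gK, gL, vNa, vK,
                                        vL, k4, leak_gated, vshift, sk, sn, s0)
            dv2, dm2, dh2, dn2 = _rhs_s(v + half * dv1, m + half * dm1,
                                        h + half * dh1, n + half * dn1,
                                        C, gNa, gK, gL, vNa, vK, vL, k4,
                                        leak_gated, vshift, sk, sn, s1)
            dv3, dm3, dh3, dn3 = _rhs_s(v + half * dv2, m + half * dm2,
                                        h + half * dh2, n + half * dn2,
                                        C, gNa, gK, gL, vNa, vK, vL, k4,
                                        leak_gated, vshift, sk, sn, s1)
            dv4, dm4, dh4, dn4 = _rhs_s(v + dt * dv3, m + dt * dm3,
                                        h + dt * dh3, n + dt * dn3,
                                        C, gNa, gK, gL, vNa, vK, vL, k4,
                                        leak_gated, vshift, sk, sn, s2)
            v = v + sixth * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
            m = m + sixth * (dm1 + 2.0 * dm2 + 2.0 * dm3 + dm4)
            h = h + sixth * (dh1 + 2.0 * dh2 + 2.0 * dh3 + dh4)
            n = n + sixth * (dn1 + 2.0 * dn2 + 2.0 * dn3 + dn4)
            if m < 0.0:
                m = 0.0
            elif m > 1.0:
                m = 1.0
            if h < 0.0:
                h = 0.0
            elif h > 1.0:
                h = 1.0
            if n < 0.0:
                n = 0.0
            elif n > 1.0:
                n = 1.0
            out_v[i + 1, b] = v
            if record_gating:
                out_g[0, i + 1, b] = m
                out_g[1, i + 1, b] = h
                out_g[2, i + 1, b] = n
            if not math.isfinite(v):
                t_diverge = (i + 1) * dt
                break
        if t_diverge >= 0.0:
            break
    return out_v, out_g, t_diverge
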