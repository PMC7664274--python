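"""Fixed-step integrator for the single-compartment neuron model.

Conductance-based model with a transient sodium current (instantaneous
m^3 activation, first-order inactivation h), a non-inactivating
persistent sodium current (fraction of the transient conductance with a
hyperpolarized activation curve), a delayed-rectifier potassium current
(n^4) and an ohmic leak.  Rate functions follow the fast-spiking
interneuron formulation of Wang & Buzsaki, with a per-preset voltage
shift and gating temperature factors that distinguish fast-spiking from
regular-spiking presets.

Units: mV, ms, pA, nS, pF.  Gating and voltage both advance by
exponential Euler, which is unconditionally stable at the default
0.01 ms step; spike counts are invariant to halving the step.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = ["integrate_cc", "resting_state", "DT_MS"]

DT_MS = 0.01  # default integration step


@njit(cache=True)
def _rates(V, vshift):
    v = V - vshift
    x = v + 35.0
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    y = v + 34.0
    if abs(y) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * y / (1.0 - np.exp(-y / 10.0))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def integrate_cc(
    i_inj: np.ndarray,
    dt: float,
    decim: int,
    C: float,
    gL: float,
    EL: float,
    gNa: float,
    ENa: float,
    gK: float,
    EK: float,
    gNaP: float,
    vshift: float,
    phi_h: float,
    phi_n: float,
    V0: float,
    h0: float,
    n0: float,
) -> np.ndarray:
    """Integrate the membrane equation under an injected-current waveform.

    ``i_inj`` is sampled at the integration step ``dt`` (ms); every
    ``decim``-th voltage sample is recorded.
    """
    n_out = i_inj.size // decim
    out = np.empty(n_out)
    V, h, n = V0, h0, n0
    k = 0
    for i in range(i_inj.size):
        am, bm, ah, bh, an, bn = _rates(V, vshift)
        hinf = ah / (ah + bh)
        tau_h = 1.0 / (phi_h * (ah + bh))
        h += (hinf - h) * (1.0 - np.exp(-dt / tau_h))
        ninf = an / (an + bn)
        tau_n = 1.0 / (phi_n * (an + bn))
        n += (ninf - n) * (1.0 - np.exp(-dt / tau_n))
        minf = am / (am + bm)
        pinf = 1.0 / (1.0 + np.exp(-(V - vshift + 48.0) / 5.0))
        g_na = gNa * minf * minf * minf * h + gNaP * pinf
        g_k = gK * n * n * n * n
        g_tot = gL + g_na + g_k
        gv = gL * EL + g_na * ENa + g_k * EK + i_inj[i]
        # exponential-Euler predictor ...
        v_inf = gv / g_tot
        Vp = v_inf + (V - v_inf) * np.exp(-dt * g_tot / C)
        # ... with a trapezoidal corrector on the voltage-dependent
        # conductances (second-order accurate; spike counts are then
        # invariant to halving the step)
        am2, bm2, _, _, _, _ = _rates(Vp, vshift)
        minf2 = am2 / (am2 + bm2)
        pinf2 = 1.0 / (1.0 + np.exp(-(Vp - vshift + 48.0) / 5.0))
        g_na2 = gNa * minf2 * minf2 * minf2 * h + gNaP * pinf2
        g_tot2 = 0.5 * (g_tot + gL + g_na2 + g_k)
        gv2 = 0.5 * (gv + gL * EL + g_na2 * ENa + g_k * EK + i_inj[i])
        v_inf2 = gv2 / g_tot2
        V = v_inf2 + (V - v_inf2) * np.exp(-dt * g_tot2 / C)
        if i % decim == decim - 1:
            out[k] = V
            k += 1
    return out


def _rates_py(V: float, vshift: float):
    v = V - vshift
    x = v + 35.0
    am = 1.0 if abs(x) < 1e-7 else 0.1 * x / (1.0 - np.exp(-x / 10.0))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    y = v + 34.0
    an = 0.1 if abs(y) < 1e-7 else 0.01 * y / (1.0 - np.exp(-y / 10.0))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


def steady_current(V, C, gL, EL, gNa, ENa, gK, EK, gNaP, vshift):
    """Net ionic current (pA, outward positive) at voltage V, gates at rest."""
    am, bm, ah, bh, an, bn = _rates_py(V, vshift)
    minf = am / (am + bm)
    hinf = ah / (ah + bh)
    ninf = an / (an + bn)
    pinf = 1.0 / (1.0 + np.exp(-(V - vshift + 48.0) / 5.0))
    return (
        gL * (V - EL)
        + (gNa * minf**3 * hinf + gNaP * pinf) * (V - ENa)
        + gK * ninf**4 * (V - EK)
    )


def resting_state(C, gL, EL, gNa, ENa, gK, EK, gNaP, vshift):
    """Resting potential and steady gate values (V_rest, h0, n0).

    Found as the most hyperpolarized zero of the steady-state I-V curve.
    """
    args = (C, gL, EL, gNa, ENa, gK, EK, gNaP, vshift)
    grid = np.arange(-110.0, -34.0, 1.0)
    f = [steady_current(v, *args) for v in grid]
    v_rest = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], f[:-1], f[1:]):
        if fa == 0.0:
            v_rest = float(a)
            break
        if fa * fb < 0:
            v_rest = brentq(lambda v: steady_current(v, *args), a, b)
            break
    if v_rest is None:
        raise ValueError("no stable resting potential below -35 mV")
    am, bm, ah, bh, an, bn = _rates_py(v_rest, vshift)
    return v_rest, ah / (ah + bh), an / (an + bn)
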