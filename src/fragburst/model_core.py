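"""Single-neuron dynamics: HH and EIF membranes, adaptation, OU noise.

The small ``@njit`` functions here are the single source of truth for the
per-step math: the network integration kernel in :mod:`fragburst.engine`
calls them directly, and the unit tests exercise them as plain functions.

Sign convention follows the membrane equation

    C dV/dt = I_intrinsic - I_syn - I_ahp - I_noise

where the synaptic and adaptation terms are conductance-based outward-positive
currents ``g * (V - E)`` and ``I_noise`` is a zero-mean OU current.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rng import rng_normal_fill

__all__ = [
    "eif_membrane_derivative",
    "hh_rates",
    "hh_derivatives",
    "hh_gate_steady_state",
    "apply_reset_and_adaptation",
    "adaptation_decay",
    "ou_noise_step",
    "hh_resting_state",
]

_EXP_CLAMP = 20.0  # caps the EIF exponential argument (divergence guard)


@njit(cache=False)
def eif_membrane_derivative(V, C, g_L, E_L, Delta_T, V_T, I_syn, I_ahp, I_noise):
    """dV/dt (mV/ms) of the exponential integrate-and-fire membrane."""
    z = (V - V_T) / Delta_T
    if z > _EXP_CLAMP:
        z = _EXP_CLAMP
    I_exp = g_L * Delta_T * np.exp(z)
    return (g_L * (E_L - V) + I_exp - I_syn - I_ahp - I_noise) / C


@njit(cache=False)
def hh_rates(V):
    """Classic HH gating rates (1/ms) at potential V (mV), rest near -65 mV.

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n).
    Singularities at V = -40 and V = -55 are series-expanded.
    """
    # m
    x = V + 40.0
    if abs(x) < 1e-6:
        alpha_m = 1.0  # limit of 0.1*x/(1-exp(-x/10)) as x->0
    else:
        alpha_m = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    # h
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    # n
    x = V + 55.0
    if abs(x) < 1e-6:
        alpha_n = 0.1
    else:
        alpha_n = 0.01 * x / (1.0 - np.exp(-x / 10.0))
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


@njit(cache=False)
def hh_derivatives(V, m, h, n, C, g_Na, g_K, g_L, E_Na, E_K, E_L, rate_scale,
                   I_syn, I_ahp, I_noise):
    """Full HH state derivative: (dV/dt, dm/dt, dh/dt, dn/dt)."""
    I_Na = g_Na * m * m * m * h * (V - E_Na)
    I_K = g_K * n * n * n * n * (V - E_K)
    I_L = g_L * (V - E_L)
    dV = (-I_Na - I_K - I_L - I_syn - I_ahp - I_noise) / C
    am, bm, ah, bh, an, bn = hh_rates(V)
    dm = rate_scale * (am * (1.0 - m) - bm * m)
    dh = rate_scale * (ah * (1.0 - h) - bh * h)
    dn = rate_scale * (an * (1.0 - n) - bn * n)
    return dV, dm, dh, dn


@njit(cache=False)
def hh_gate_steady_state(V):
    """(m_inf, h_inf, n_inf) at clamped potential V."""
    am, bm, ah, bh, an, bn = hh_rates(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def hh_resting_state(p, I_ext=0.0, tol=1e-10, max_iter=200000):
    """Resting fixed point (V, m, h, n) of an HH neuron under constant drive.

    Found by relaxation (long subthreshold integration); used for initial
    conditions and for fixed-point tests.
    """
    V = p.E_L
    m, h, n = hh_gate_steady_state(V)
    dt = 0.02
    for _ in range(max_iter):
        dV, dm, dh, dn = hh_derivatives(
            V, m, h, n, p.C, p.g_Na, p.g_K, p.g_L, p.E_Na, p.E_K, p.E_L,
            p.rate_scale, -I_ext, 0.0, 0.0,
        )
        V += dt * dV
        m += dt * dm
        h += dt * dh
        n += dt * dn
        if abs(dV) < tol and abs(dm) < tol and abs(dh) < tol and abs(dn) < tol:
            break
    return V, m, h, n


@njit(cache=False)
def apply_reset_and_adaptation(V, g_ahp, V_reset, delta, t):
    """Post-spike update: hard reset (EIF) and adaptation increment.

    Returns (V', g_ahp', last_spike_time).  For HH neurons the caller passes
    V unchanged as ``V_reset`` (no reset; the membrane repolarizes itself).
    """
    return V_reset, g_ahp + delta, t


@njit(cache=False)
def adaptation_decay(g_ahp, dt, tau):
    """Exact exponential decay of the adaptation conductance over dt."""
    return g_ahp * np.exp(-dt / tau)


@njit(cache=False)
def ou_noise_step(eta, sigma, tau_noise, dt, state, scratch):
    """Exact OU update of the noise-current vector ``eta`` (in place).

    Stationary sd = sigma, correlation time = tau_noise.  ``state`` is an
    xorshift stream from :func:`fragburst._rng.seed_stream`; ``scratch`` a
    work array of the same length as ``eta``.  sigma = 0 gives exactly 0.
    """
    n = eta.shape[0]
    if sigma == 0.0:
        for i in range(n):
            eta[i] = 0.0
        return eta
    a = np.exp(-dt / tau_noise)
    b = sigma * np.sqrt(1.0 - a * a)
    rng_normal_fill(state, scratch)
    for i in range(n):
        eta[i] = a * eta[i] + b * scratch[i]
    return eta
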