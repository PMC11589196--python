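"""Synaptic transmission and short-term plasticity.

Presynaptic resource dynamics (Tsodyks-Markram):

* **STD** — available resource fraction x recovers as dx/dt = (1-x)/tau_D
  between spikes; on each presynaptic spike a fraction ``U*x`` is released
  and the postsynaptic amplitude is the weight times the *pre-spike* x.
* **STP** — adds the facilitating release probability u: on each spike u
  jumps first by ``U*(1-u)``, then ``u'*x`` is released, and the amplitude
  carries the factor ``u'*x``.
* **Asynchronous release** — stochastic vesicle release from the same pool
  x at rate ``u_ar`` (1/ms), which rises toward its saturation on spikes
  and decays with ``tau_ar``; the number of released vesicles per step is
  binomial B(floor(x/x0), u_ar*dt), approximated by a clipped rounded
  normal.

Postsynaptic receptors: open-channel fraction s jumps on (delayed) spike
arrival and decays exponentially — fast AMPA plus slow Mg-blocked NMDA, or
a single generic channel for the minimal model.

All between-spike updates use the exact exponential solutions, so the
clock-driven kernel and event-driven evaluation agree to rounding error.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rng import rng_normal

__all__ = [
    "std_recover",
    "std_on_spike",
    "stp_recover_u",
    "stp_on_spike",
    "async_uar_on_spike",
    "async_release_step",
    "nmda_block",
    "receptor_decay",
    "run_std_event_driven",
    "run_stp_event_driven",
]


@njit(cache=False)
def std_recover(x, dt, tau_D):
    """Exact resource recovery over an interval dt: dx/dt = (1-x)/tau_D."""
    return 1.0 - (1.0 - x) * np.exp(-dt / tau_D)


@njit(cache=False)
def std_on_spike(x, U):
    """Depression-only spike update.

    Returns (release, amplitude_factor, x') = (U*x, x, x*(1-U)): the
    postsynaptic weight is multiplied by the pre-spike x while a fraction
    U*x of the pool is consumed.
    """
    return U * x, x, x * (1.0 - U)


@njit(cache=False)
def stp_recover_u(u, dt, tau_F, U):
    """Facilitation decay toward baseline U between spikes (exact)."""
    return U + (u - U) * np.exp(-dt / tau_F)


@njit(cache=False)
def stp_on_spike(x, u, U, _tau_F=0.0):
    """Depression+facilitation spike update.

    u jumps first (u' = u + U*(1-u)), then u'*x is released and subtracted.
    Returns (release, amplitude_factor, x', u') with amplitude u'*x.
    """
    u2 = u + U * (1.0 - u)
    release = u2 * x
    return release, release, x - release, u2


@njit(cache=False)
def async_uar_on_spike(u_ar, U_ar, jump):
    """Asynchronous release rate jumps toward its saturation on a spike."""
    return u_ar + jump * (U_ar - u_ar)


@njit(cache=False)
def async_release_step(x, u_ar, dt, x0, state):
    """One stochastic asynchronous-release draw.

    n ~ B(N, p) with N = floor(x/x0), p = u_ar*dt, approximated by a normal
    with the binomial mean and variance, rounded and clipped to [0, N].
    Returns (q_ar, x') with q_ar = x0*n and the shared pool depleted.
    """
    p = u_ar * dt
    if p <= 0.0 or x < x0:
        return 0.0, x
    N = int(np.floor(x / x0))
    mean = N * p
    sd = np.sqrt(N * p * (1.0 - p))
    draw = mean + sd * rng_normal(state)
    n = np.rint(draw)
    if n < 0.0:
        n = 0.0
    elif n > N:
        n = float(N)
    q = x0 * n
    return q, x - q


@njit(cache=False)
def nmda_block(V, mg_conc):
    """Jahr-Stevens magnesium-block factor B(V), sigmoid in V, B(-inf)=0."""
    return 1.0 / (1.0 + mg_conc * np.exp(-0.062 * V) / 3.57)


@njit(cache=False)
def receptor_decay(s, dt, tau):
    """Exact open-channel decay over dt."""
    return s * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# Event-driven evaluation on explicit spike trains.  These are the exact
# closed-form references used to validate the clock-driven kernel and the
# oracles for steady-state tests; they are also handy for quick synaptic
# characterization (paired-pulse ratios etc.).


def run_std_event_driven(spike_times, U, tau_D, x_init=1.0):
    """Resource x evaluated just before/after each spike under pure STD.

    Returns (x_pre, release, x_post) arrays aligned with ``spike_times``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = spike_times.size
    x_pre = np.empty(n)
    release = np.empty(n)
    x_post = np.empty(n)
    x = x_init
    t_last = None
    for i, t in enumerate(spike_times):
        if t_last is not None:
            x = std_recover(x, t - t_last, tau_D)
        x_pre[i] = x
        rel, _amp, x = std_on_spike(x, U)
        release[i] = rel
        x_post[i] = x
        t_last = t
    return x_pre, release, x_post


def run_stp_event_driven(spike_times, U, tau_D, tau_F, x_init=1.0, u_init=None):
    """(x, u, amplitude) trajectories on a spike train under the STP model.

    Amplitude is the postsynaptic efficacy factor u'*x at each spike.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = spike_times.size
    if u_init is None:
        u_init = U
    x_pre = np.empty(n)
    u_post = np.empty(n)
    amp = np.empty(n)
    x, u = x_init, u_init
    t_last = None
    for i, t in enumerate(spike_times):
        if t_last is not None:
            dt = t - t_last
            x = std_recover(x, dt, tau_D)
            u = stp_recover_u(u, dt, tau_F, U)
        x_pre[i] = x
        _rel, a, x, u = stp_on_spike(x, u, U)
        amp[i] = a
        u_post[i] = u
        t_last = t
    return x_pre, u_post, amp
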