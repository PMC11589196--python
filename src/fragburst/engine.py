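"""Time-stepped network integration with delayed spike delivery.

One numba kernel integrates the whole network: exponential Euler for all
conductance/gating/resource variables (their between-spike dynamics are
linear, so the per-step decay is exact) and forward Euler for the membrane
potential.  Spikes are delivered through a circular per-step arrival buffer
at axonal-delay resolution; asynchronous vesicle release bypasses the delay
line (it is generated at the terminal).

Scheduled parameter switches split the run into segments; the full state
(membrane, gating, plasticity, delay buffer, RNG streams) is carried across
segment boundaries bit-exactly, so a switch to an identical value leaves
the run unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from numba import njit

from . import model_core as mc
from . import synapses as syn
from ._rng import seed_stream
from .network import NetworkModel
from .params import ScheduleEvent, SimulationConfig
from .recording import Recording

__all__ = [
    "SimulationResult",
    "run_simulation",
    "apply_schedule",
    "save_result",
    "load_result",
]

STATE_COLUMNS = ["x", "u", "u_ar", "g_sahp", "g_mahp", "I_syn"]

# --- index maps into the packed scalar-parameter arrays -----------------
_DT, _C, _GNA, _GK, _GL, _ENA, _EK, _EL, _RATE, _SPKTHR = range(10)
_ECAP, _EGL, _EEL, _DELTAT, _VT, _VTHRES, _VRESET = range(10, 17)
_DSAHP, _TAUSAHP, _EAHP, _DMAHP, _TAUMAHP = range(17, 22)
_SIGMA, _TAUNOISE = 22, 23
_GA, _GN, _TAUA, _TAUN, _ESYN, _MG = range(24, 30)
_U, _TAUD, _TAUF = 30, 31, 32
_UAR, _JUMPAR, _TAUAR, _X0 = range(33, 37)
_VREST, _LOCKOUT, _TREF = 37, 38, 39
_NPARAMS = 40

_KIND, _MECH, _NMDA, _MAHP, _RECSTRIDE, _STATESTRIDE, _GSTEP0, _NSTEPS = range(8)
_NFLAGS = 8


@njit(cache=False)
def _kernel(P, F, I_ext, indptr, targets, w_eff, dsteps, buf, pos0,
            e_indptr, e_neurons, elec_out, rec_idx0, state_out, state_idx0,
            spk_n, spk_t, spk_count0, V, m, h, ng, gs, gm, eta, x, u, uar,
            sA, sN, last_det, ref_until, noise_state, async_state, scratch):
    n = V.shape[0]
    dt = P[_DT]
    L = buf.shape[0]
    kind = F[_KIND]
    mech = F[_MECH]
    use_nmda = F[_NMDA]
    use_mahp = F[_MAHP]
    rec_stride = F[_RECSTRIDE]
    state_stride = F[_STATESTRIDE]
    gstep0 = F[_GSTEP0]
    n_steps = F[_NSTEPS]

    # exact per-step decay factors
    dA = np.exp(-dt / P[_TAUA])
    dN = np.exp(-dt / P[_TAUN])
    dS = np.exp(-dt / P[_TAUSAHP])
    dM = np.exp(-dt / P[_TAUMAHP])
    dD = np.exp(-dt / P[_TAUD])
    dF_ = np.exp(-dt / P[_TAUF])
    dAR = np.exp(-dt / P[_TAUAR])

    pos = pos0
    rec_idx = rec_idx0
    state_idx = state_idx0
    spk_count = spk_count0
    spk_cap = spk_n.shape[0]
    spikers = np.empty(n, dtype=np.int64)
    status = 0

    for step in range(n_steps):
        gstep = gstep0 + step + 1
        t = gstep * dt

        # 1. exact exponential decays of all linear state variables
        for i in range(n):
            sA[i] *= dA
            sN[i] *= dN
            gs[i] *= dS
            if use_mahp == 1:
                gm[i] *= dM
            if mech >= 1:
                x[i] = 1.0 - (1.0 - x[i]) * dD
            if mech >= 2:
                u[i] = P[_U] + (u[i] - P[_U]) * dF_
            if mech == 3:
                uar[i] *= dAR

        # 2. membrane noise (exact OU update)
        mc.ou_noise_step(eta, P[_SIGMA], P[_TAUNOISE], dt, noise_state, scratch)

        # 3. deliver delayed spike arrivals due this step
        for i in range(n):
            a = buf[pos, i]
            if a != 0.0:
                sA[i] += a
                sN[i] += a
                buf[pos, i] = 0.0

        # 4. currents and membrane integration; spike detection
        n_spk = 0
        isyn_sum = 0.0
        for i in range(n):
            v = V[i]
            Isyn = P[_GA] * sA[i] * (v - P[_ESYN])
            if use_nmda == 1:
                Isyn += (
                    P[_GN] * sN[i] * syn.nmda_block(v, P[_MG]) * (v - P[_ESYN])
                )
            isyn_sum += Isyn
            Iahp = gs[i] * (v - P[_EAHP])
            if use_mahp == 1:
                Iahp += gm[i] * (v - P[_EAHP])
            Iinj = eta[i] + I_ext[i]

            if kind == 0:  # Hodgkin-Huxley
                dV, _dm, _dh, _dn = mc.hh_derivatives(
                    v, m[i], h[i], ng[i], P[_C], P[_GNA], P[_GK], P[_GL],
                    P[_ENA], P[_EK], P[_EL], P[_RATE], Isyn, Iahp, -Iinj,
                )
                # exponential Euler on the gates, forward Euler on V
                am, bm, ah, bh, an, bn = mc.hh_rates(v)
                rs = P[_RATE]
                km = rs * (am + bm)
                kh = rs * (ah + bh)
                kn = rs * (an + bn)
                m[i] = am / (am + bm) + (m[i] - am / (am + bm)) * np.exp(-dt * km)
                h[i] = ah / (ah + bh) + (h[i] - ah / (ah + bh)) * np.exp(-dt * kh)
                ng[i] = an / (an + bn) + (ng[i] - an / (an + bn)) * np.exp(-dt * kn)
                v_new = v + dt * dV
                if not np.isfinite(v_new):
                    status = 1
                    break
                V[i] = v_new
                if (
                    v < P[_SPKTHR]
                    and v_new >= P[_SPKTHR]
                    and t - last_det[i] >= P[_LOCKOUT]
                ):
                    last_det[i] = t
                    spikers[n_spk] = i
                    n_spk += 1
            else:  # exponential integrate-and-fire
                if t < ref_until[i]:
                    V[i] = P[_VRESET]
                    continue
                dV = mc.eif_membrane_derivative(
                    v, P[_ECAP], P[_EGL], P[_EEL], P[_DELTAT], P[_VT],
                    Isyn, Iahp, -Iinj,
                )
                v_new = v + dt * dV
                if not np.isfinite(v_new):
                    status = 1
                    break
                if v_new > P[_VTHRES]:
                    V[i] = P[_VRESET]
                    ref_until[i] = t + P[_TREF]
                    last_det[i] = t
                    spikers[n_spk] = i
                    n_spk += 1
                else:
                    V[i] = v_new
        if status != 0:
            break

        # 5. per-spike plasticity updates and delayed scatter to targets
        for k in range(n_spk):
            j = spikers[k]
            gs[j] += P[_DSAHP]
            if use_mahp == 1:
                gm[j] += P[_DMAHP]
            if mech == 0:
                amp = 1.0
            elif mech == 1:
                _rel, amp, x[j] = syn.std_on_spike(x[j], P[_U])
            else:
                _rel, amp, x[j], u[j] = syn.stp_on_spike(x[j], u[j], P[_U])
                if mech == 3:
                    uar[j] = syn.async_uar_on_spike(uar[j], P[_UAR], P[_JUMPAR])
            if spk_count >= spk_cap:
                status = 2
                break
            spk_n[spk_count] = j
            spk_t[spk_count] = t
            spk_count += 1
            for e in range(indptr[j], indptr[j + 1]):
                row = (pos + dsteps[e]) % L
                buf[row, targets[e]] += w_eff[e] * amp
        if status != 0:
            break

        # 6. asynchronous release: immediate (non-delayed) receptor drive
        if mech == 3:
            for j in range(n):
                q, x[j] = syn.async_release_step(
                    x[j], uar[j], dt, P[_X0], async_state
                )
                if q > 0.0:
                    for e in range(indptr[j], indptr[j + 1]):
                        tgt = targets[e]
                        sA[tgt] += w_eff[e] * q
                        sN[tgt] += w_eff[e] * q

        pos = (pos + 1) % L

        # 7. recording
        if gstep % rec_stride == 0 and rec_idx < elec_out.shape[1]:
            for el in range(e_indptr.shape[0] - 1):
                lo = e_indptr[el]
                hi = e_indptr[el + 1]
                if hi > lo:
                    acc = 0.0
                    for q_ in range(lo, hi):
                        acc += V[e_neurons[q_]] - P[_VREST]
                    elec_out[el, rec_idx] = 1000.0 * acc / (hi - lo)  # mV->µV
            rec_idx += 1
        if gstep % state_stride == 0 and state_idx < state_out.shape[0]:
            mx = 0.0
            mu = 0.0
            muar = 0.0
            mgs = 0.0
            mgm = 0.0
            for i in range(n):
                mx += x[i]
                mu += u[i]
                muar += uar[i]
                mgs += gs[i]
                mgm += gm[i]
            state_out[state_idx, 0] = mx / n
            state_out[state_idx, 1] = mu / n
            state_out[state_idx, 2] = muar / n
            state_out[state_idx, 3] = mgs / n
            state_out[state_idx, 4] = mgm / n
            state_out[state_idx, 5] = isyn_sum / n
            state_idx += 1

    return status, spk_count, pos, rec_idx, state_idx


@dataclass
class SimulationResult:
    """Spike trains + virtual-electrode recording + decimated state traces."""

    spike_trains: list  # per-neuron sorted spike times (ms)
    recording: Recording  # virtual electrodes @ record_fs, µV
    state_traces: pd.DataFrame  # population means at state_stride_ms
    sim_config: SimulationConfig
    provenance: dict

    @property
    def n_neurons(self) -> int:
        return len(self.spike_trains)

    def spike_dataframe(self) -> pd.DataFrame:
        """All spikes as a (neuron_id, t_ms) table."""
        ids = np.concatenate(
            [np.full(st.size, i) for i, st in enumerate(self.spike_trains)]
        ) if any(st.size for st in self.spike_trains) else np.empty(0, dtype=int)
        ts = (
            np.concatenate(self.spike_trains)
            if any(st.size for st in self.spike_trains)
            else np.empty(0)
        )
        order = np.argsort(ts, kind="mergesort")
        return pd.DataFrame({"neuron_id": ids[order], "t_ms": ts[order]})


def apply_schedule(model: NetworkModel, event) -> NetworkModel:
    """Apply one scheduled parameter switch, returning the updated model.

    ``event`` is a :class:`ScheduleEvent` or a (time_s, path, value) tuple.
    Unknown parameter paths raise ``KeyError``.
    """
    if not isinstance(event, ScheduleEvent):
        event = ScheduleEvent(*event)
    return model.with_param(event.path, event.value)


def _pack_params(model: NetworkModel, dt: float) -> tuple:
    cfg = model.config
    P = np.zeros(_NPARAMS)
    F = np.zeros(_NFLAGS, dtype=np.int64)
    hh, eif, ad, nz, sp, ar = (
        cfg.hh, cfg.eif, cfg.adaptation, cfg.noise, cfg.synapse,
        cfg.async_release,
    )
    P[_DT] = dt
    P[[_C, _GNA, _GK, _GL, _ENA, _EK, _EL, _RATE, _SPKTHR]] = (
        hh.C, hh.g_Na, hh.g_K, hh.g_L, hh.E_Na, hh.E_K, hh.E_L,
        hh.rate_scale, hh.spike_threshold,
    )
    P[[_ECAP, _EGL, _EEL, _DELTAT, _VT, _VTHRES, _VRESET]] = (
        eif.C, eif.g_L, eif.E_L, eif.Delta_T, eif.V_T, eif.V_thres, eif.V_reset,
    )
    P[[_DSAHP, _TAUSAHP, _EAHP]] = ad.delta, ad.tau_sahp, ad.E_K_ahp
    P[_DMAHP] = ad.delta * ad.mahp_multiplier
    P[_TAUMAHP] = ad.tau_mahp
    P[[_SIGMA, _TAUNOISE]] = nz.sigma, nz.tau_noise
    generic = sp.receptors == "generic"
    P[_GA] = sp.g_syn_max
    P[_GN] = 0.0 if generic else sp.g_syn_max * sp.nmda_ampa_ratio
    P[_TAUA] = sp.tau_syn if generic else sp.tau_AMPA
    P[_TAUN] = sp.tau_NMDA_decay
    P[[_ESYN, _MG]] = sp.E_syn, sp.mg_conc
    P[[_U, _TAUD, _TAUF]] = sp.U, sp.tau_D, sp.tau_F
    P[[_UAR, _JUMPAR, _TAUAR, _X0]] = ar.U_ar, ar.jump, ar.tau_ar, ar.x0
    # electrode deviation reference: the resting potential (-65 mV for the
    # HH kinetics used here; E_L itself is not the HH rest)
    P[_VREST] = -65.0 if cfg.neuron_kind == "hh" else eif.E_L
    P[_LOCKOUT] = hh.spike_lockout
    P[_TREF] = eif.t_ref

    F[_KIND] = 0 if cfg.neuron_kind == "hh" else 1
    F[_MECH] = {"none": 0, "std": 1, "stp": 2, "async": 3}[sp.mechanism]
    F[_NMDA] = 0 if generic else 1
    F[_MAHP] = 1 if ad.variant == "mahp" else 0
    return P, F


def run_simulation(model: NetworkModel, sim: SimulationConfig) -> SimulationResult:
    """Integrate the network and return spikes, recording, state traces.

    Deterministic: the same (model, sim) pair gives bit-identical results.
    Raises ``FloatingPointError`` on numerical blow-up (reduce dt) and
    ``ValueError`` for a time step too coarse for the asynchronous-release
    rate (requires ``u_ar * dt <= 1``).
    """
    cfg = model.config
    cfg.validate()
    sim.validate(cfg.neuron_kind)
    dt = sim.dt
    if cfg.synapse.mechanism == "async" and cfg.async_release.U_ar * dt > 1.0:
        raise ValueError("u_ar * dt > 1: time step too coarse for async release")

    n = model.n_neurons
    n_steps_total = int(round(sim.duration * 1000.0 / dt))
    rec_stride = int(round(1000.0 / sim.record_fs / dt))
    state_stride = max(1, int(round(sim.state_stride_ms / dt)))

    # seeds: master -> noise stream, async stream, init jitter, measurement
    ss = np.random.SeedSequence(sim.seed)
    s_noise, s_async, s_init, s_meas = [
        int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(4)
    ]
    noise_state = seed_stream(s_noise, 1)
    async_state = seed_stream(s_async, 2)
    r_init = np.random.default_rng(s_init)

    # initial conditions: V near rest with small jitter; x=1, u=U, g_ahp=0
    if cfg.neuron_kind == "hh":
        v0 = -65.0
        V = np.full(n, v0) + r_init.normal(0.0, 0.5, n)
        m0, h0, n0 = mc.hh_gate_steady_state(v0)
        m = np.full(n, m0)
        h = np.full(n, h0)
        ng = np.full(n, n0)
    else:
        V = np.full(n, cfg.eif.E_L) + r_init.normal(0.0, 0.5, n)
        m = np.zeros(n)
        h = np.zeros(n)
        ng = np.zeros(n)
    gs = np.zeros(n)
    gm = np.zeros(n)
    eta = np.zeros(n)
    x = np.ones(n)
    u = np.full(n, cfg.synapse.U)
    uar = np.zeros(n)
    sA = np.zeros(n)
    sN = np.zeros(n)
    last_det = np.full(n, -1e12)
    ref_until = np.full(n, -1e12)
    scratch = np.empty(n)

    dsteps = np.maximum(1, np.round(model.delays / dt)).astype(np.int64)
    L = int(dsteps.max()) + 1 if dsteps.size else 2
    buf = np.zeros((L, n))

    n_rec = n_steps_total // rec_stride
    n_state = n_steps_total // state_stride
    n_elec = model.elec_indptr.size - 1
    elec_out = np.zeros((n_elec, n_rec), dtype=np.float32)
    state_out = np.zeros((n_state, len(STATE_COLUMNS)))
    spk_cap = int(n * sim.duration * 400) + 1024
    spk_n = np.empty(spk_cap, dtype=np.int64)
    spk_t = np.empty(spk_cap)

    # split into segments at scheduled switch times
    events = sorted(
        (ev if isinstance(ev, ScheduleEvent) else ScheduleEvent(*ev)
         for ev in sim.schedule),
        key=lambda e: e.time_s,
    )
    boundaries = [int(round(ev.time_s * 1000.0 / dt)) for ev in events]
    segment_edges = [0] + boundaries + [n_steps_total]

    pos = 0
    rec_idx = 0
    state_idx = 0
    spk_count = 0
    current = model
    for si in range(len(segment_edges) - 1):
        if si > 0:
            current = apply_schedule(current, events[si - 1])
        g0, g1 = segment_edges[si], segment_edges[si + 1]
        if g1 <= g0:
            continue
        P, F = _pack_params(current, dt)
        F[_RECSTRIDE] = rec_stride
        F[_STATESTRIDE] = state_stride
        F[_GSTEP0] = g0
        F[_NSTEPS] = g1 - g0
        w_eff = current.weights * current.config.synapse.S
        status, spk_count, pos, rec_idx, state_idx = _kernel(
            P, F, current.I_ext, current.indptr, current.targets, w_eff,
            dsteps, buf, pos, current.elec_indptr, current.elec_neurons,
            elec_out, rec_idx, state_out, state_idx, spk_n, spk_t, spk_count,
            V, m, h, ng, gs, gm, eta, x, u, uar, sA, sN, last_det, ref_until,
            noise_state, async_state, scratch,
        )
        if status == 1:
            raise FloatingPointError(
                "membrane potential became non-finite (numerical blow-up); "
                "reduce dt"
            )
        if status == 2:
            raise RuntimeError("spike buffer overflow: firing rate exceeds cap")

    # measurement noise on the electrode channels
    r_meas = np.random.default_rng(s_meas)
    noise_sd = cfg.electrodes.noise_sd
    voltage = elec_out[:, :rec_idx].astype(np.float64)
    if noise_sd > 0:
        voltage = voltage + r_meas.normal(0.0, noise_sd, voltage.shape)
    rec = Recording(voltage=voltage, fs=sim.record_fs)

    trains = []
    spk_n = spk_n[:spk_count]
    spk_t = spk_t[:spk_count]
    for i in range(n):
        ti = np.sort(spk_t[spk_n == i])
        trains.append(ti)

    t_state = (np.arange(1, state_idx + 1) * state_stride * dt) / 1000.0
    states = pd.DataFrame(state_out[:state_idx], columns=STATE_COLUMNS)
    states.insert(0, "t_s", t_state)

    provenance = {
        "seed": sim.seed,
        "network_seed": model.seed,
        "config": dataclasses.asdict(cfg),
        "dt_ms": dt,
        "duration_s": sim.duration,
    }
    return SimulationResult(
        spike_trains=trains,
        recording=rec,
        state_traces=states,
        sim_config=sim,
        provenance=provenance,
    )


def save_result(result: SimulationResult, path) -> None:
    """Write a result to HDF5 (/spikes/neuron_i, /recording/*, /state/*)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        for i, st in enumerate(result.spike_trains):
            g.create_dataset(f"neuron_{i}", data=st)
        gr = f.create_group("recording")
        gr.create_dataset("voltage", data=result.recording.voltage)
        gr.create_dataset("fs", data=result.recording.fs)
        gr.attrs["channel_ids"] = [str(c) for c in result.recording.channel_ids]
        gsrp = f.create_group("state")
        gsrp.create_dataset("t_s", data=result.state_traces["t_s"].to_numpy())
        for c in STATE_COLUMNS:
            gsrp.create_dataset(c, data=result.state_traces[c].to_numpy())
        f.attrs["provenance"] = json.dumps(result.provenance)


def load_result(path) -> SimulationResult:
    """Read a result written by :func:`save_result`."""
    with h5py.File(path, "r") as f:
        n = len(f["spikes"])
        trains = [np.asarray(f[f"spikes/neuron_{i}"]) for i in range(n)]
        rec = Recording(
            voltage=np.asarray(f["recording/voltage"]),
            fs=float(f["recording/fs"][()]),
            channel_ids=list(f["recording"].attrs["channel_ids"]),
        )
        data = {c: np.asarray(f[f"state/{c}"]) for c in STATE_COLUMNS}
        states = pd.DataFrame(data)
        states.insert(0, "t_s", np.asarray(f["state/t_s"]))
        provenance = json.loads(f.attrs["provenance"])
    return SimulationResult(
        spike_trains=trains,
        recording=rec,
        state_traces=states,
        sim_config=SimulationConfig(
            duration=provenance["duration_s"], dt=provenance["dt_ms"],
            seed=provenance["seed"],
        ),
        provenance=provenance,
    )
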