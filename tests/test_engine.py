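"""Network integration: determinism, causality, plasticity agreement, schedules."""

import numpy as np
import pytest

from fragburst.engine import apply_schedule, load_result, run_simulation, save_result
from fragburst.network import build_network
from fragburst.params import (
    ScheduleEvent,
    SimulationConfig,
    default_minimal_config,
    replace_param,
)
from fragburst.synapses import std_on_spike, std_recover


def _quiet_two_neuron_config(I_ext=150.0, U=0.3, tau_D=100.0, delta=0.0,
                             w=1e-6):
    """Two tonically driven EIF neurons with negligible coupling."""
    cfg = default_minimal_config()
    cfg = replace_param(cfg, "topology.n_neurons", 2)
    cfg = replace_param(cfg, "topology.connection_prob", 1.0)
    cfg = replace_param(cfg, "noise.sigma", 0.0)
    cfg = replace_param(cfg, "heterogeneity.I_ext_mean", I_ext)
    cfg = replace_param(cfg, "synapse.w_mean", w)
    cfg = replace_param(cfg, "synapse.U", U)
    cfg = replace_param(cfg, "synapse.tau_D", tau_D)
    cfg = replace_param(cfg, "adaptation.delta", delta)
    return cfg


class TestBasics:
    def test_quiescent_network_stays_silent(self):
        cfg = default_minimal_config()
        cfg = replace_param(cfg, "noise.sigma", 0.0)
        cfg = replace_param(cfg, "heterogeneity.I_ext_mean", 0.0)
        model = build_network(cfg, seed=0)
        res = run_simulation(model, SimulationConfig(duration=5.0, seed=0))
        assert sum(st.size for st in res.spike_trains) == 0

    def test_same_seed_bit_identical(self):
        model = build_network(default_minimal_config(), seed=2)
        sim = SimulationConfig(duration=8.0, seed=5)
        r1 = run_simulation(model, sim)
        r2 = run_simulation(model, sim)
        for a, b in zip(r1.spike_trains, r2.spike_trains):
            assert np.array_equal(a, b)
        assert np.array_equal(r1.recording.voltage, r2.recording.voltage)

    def test_spike_times_strictly_increasing_and_recording_length(self):
        model = build_network(default_minimal_config(), seed=1)
        sim = SimulationConfig(duration=6.0, seed=1)
        res = run_simulation(model, sim)
        for st in res.spike_trains:
            if st.size > 1:
                assert np.all(np.diff(st) > 0)
        assert abs(res.recording.n_samples - 6.0 * 10000) <= 1

    def test_async_dt_too_coarse_rejected(self):
        cfg = replace_param(default_minimal_config(), "synapse.mechanism", "async")
        cfg = replace_param(cfg, "async_release.U_ar", 0.9)
        model = build_network(cfg, seed=0)
        with pytest.raises(ValueError, match="u_ar"):
            run_simulation(model, SimulationConfig(dt=2.0, duration=1.0, seed=0,
                                                   record_fs=500.0))

    def test_result_hdf5_round_trip(self, tmp_path):
        model = build_network(default_minimal_config(), seed=3)
        res = run_simulation(model, SimulationConfig(duration=3.0, seed=3))
        p = tmp_path / "result.h5"
        save_result(res, p)
        back = load_result(p)
        for a, b in zip(res.spike_trains, back.spike_trains):
            assert np.array_equal(a, b)
        assert np.allclose(back.recording.voltage, res.recording.voltage)
        assert np.allclose(
            back.state_traces["x"], res.state_traces["x"]
        )


class TestSingleNeuronIntegration:
    def test_dt_halving_spike_time_convergence(self):
        """Early spike times shift < 0.5 ms under dt halving, and the
        firing period converges first-order (tonic-drive phase drift is the
        only accumulating error)."""
        cfg = _quiet_two_neuron_config()
        cfg = replace_param(cfg, "topology.n_neurons", 1)
        cfg = replace_param(cfg, "topology.connection_prob", 0.0)
        model = build_network(cfg, seed=0)
        trains = {}
        for dt in (0.05, 0.025, 0.0125):
            res = run_simulation(model, SimulationConfig(dt=dt, duration=10.0,
                                                         seed=0))
            trains[dt] = res.spike_trains[0]
        a, b = trains[0.05], trains[0.025]
        assert a.size > 100
        # O(dt) per-cycle phase drift: compare before it accumulates
        k = min(10, a.size, b.size)
        assert np.max(np.abs(a[:k] - b[:k])) < 0.5
        p = {dt: np.mean(np.diff(st)) for dt, st in trains.items()}
        # period error is O(dt): bounded by ~dt at each refinement level
        assert abs(p[0.05] - p[0.0125]) < 2 * 0.05
        assert abs(p[0.025] - p[0.0125]) < 2 * 0.025

    def test_spike_count_non_increasing_in_adaptation(self):
        counts = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            cfg = _quiet_two_neuron_config(delta=delta)
            cfg = replace_param(cfg, "topology.n_neurons", 1)
            cfg = replace_param(cfg, "topology.connection_prob", 0.0)
            model = build_network(cfg, seed=0)
            res = run_simulation(model, SimulationConfig(duration=10.0, seed=0))
            counts.append(res.spike_trains[0].size)
        assert counts[0] > 0
        assert np.all(np.diff(counts) <= 0)


class TestPlasticityInKernel:
    def test_clock_driven_std_matches_event_driven_oracle(self):
        """Mean resource trace from the kernel equals the closed-form
        event-driven evaluation on the kernel's own spike trains."""
        dt = 0.05
        U, tau_D = 0.3, 100.0
        cfg = _quiet_two_neuron_config(U=U, tau_D=tau_D)
        model = build_network(cfg, seed=0)
        sim = SimulationConfig(dt=dt, duration=5.0, seed=0)
        res = run_simulation(model, sim)
        assert all(st.size > 5 for st in res.spike_trains)

        t_samples = res.state_traces["t_s"].to_numpy() * 1000.0  # ms
        oracle = np.zeros((2, t_samples.size))
        for j in range(2):
            spikes = res.spike_trains[j]
            for k, ts in enumerate(t_samples):
                x = 1.0
                t_prev = 0.0
                for s in spikes[spikes <= ts + 1e-9]:
                    x = std_recover(x, s - t_prev, tau_D)
                    _, _, x = std_on_spike(x, U)
                    t_prev = s
                x = std_recover(x, ts - t_prev, tau_D)
                oracle[j, k] = x
        mean_oracle = oracle.mean(axis=0)
        kernel_x = res.state_traces["x"].to_numpy()
        assert np.max(np.abs(kernel_x - mean_oracle)) < 1e-9

    def test_uar_zero_reduces_async_to_stp(self):
        cfg = default_minimal_config()
        cfg = replace_param(cfg, "synapse.mechanism", "async")
        cfg = replace_param(cfg, "async_release.U_ar", 0.0)
        model = build_network(cfg, seed=4)
        sim = SimulationConfig(duration=6.0, seed=4)
        res_async = run_simulation(model, sim)
        cfg2 = replace_param(cfg, "synapse.mechanism", "stp")
        res_stp = run_simulation(build_network(cfg2, seed=4), sim)
        for a, b in zip(res_async.spike_trains, res_stp.spike_trains):
            assert np.array_equal(a, b)


class TestSchedule:
    def test_unknown_path_rejected(self):
        model = build_network(default_minimal_config(), seed=0)
        with pytest.raises(KeyError):
            apply_schedule(model, (1.0, "synapse.nonexistent", 1.0))

    def test_switch_to_identical_value_changes_nothing(self):
        cfg = default_minimal_config()
        model = build_network(cfg, seed=6)
        sim_plain = SimulationConfig(duration=8.0, seed=6)
        sim_sched = SimulationConfig(
            duration=8.0, seed=6,
            schedule=[ScheduleEvent(4.0, "synapse.U", cfg.synapse.U)],
        )
        r1 = run_simulation(model, sim_plain)
        r2 = run_simulation(model, sim_sched)
        for a, b in zip(r1.spike_trains, r2.spike_trains):
            assert np.array_equal(a, b)
        assert np.array_equal(r1.recording.voltage, r2.recording.voltage)

    def test_pre_switch_dynamics_unaffected_by_future_switch(self):
        cfg = default_minimal_config()
        model = build_network(cfg, seed=7)
        t_switch = 4.0
        sim_plain = SimulationConfig(duration=8.0, seed=7)
        sim_sched = SimulationConfig(
            duration=8.0, seed=7,
            schedule=[ScheduleEvent(t_switch, "synapse.U", 0.9)],
        )
        r1 = run_simulation(model, sim_plain)
        r2 = run_simulation(model, sim_sched)
        for a, b in zip(r1.spike_trains, r2.spike_trains):
            assert np.array_equal(
                a[a < t_switch * 1000.0], b[b < t_switch * 1000.0]
            )

    def test_parameter_isolation(self):
        model = build_network(default_minimal_config(), seed=0)
        updated = apply_schedule(model, (1.0, "synapse.U", 0.77))
        assert updated.config.synapse.U == 0.77
        # everything else identical, including the random draws
        assert np.array_equal(updated.weights, model.weights)
        assert updated.config.synapse.tau_D == model.config.synapse.tau_D
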