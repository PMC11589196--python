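"""Network construction: topology, heterogeneity, layout, virtual electrodes.

A :class:`NetworkModel` is a fully materialized network — parameter blocks
plus the random draws (adjacency, weights, delays, positions, per-neuron
external drive) — reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import ElectrodeLayout, NetworkConfig, replace_param

__all__ = [
    "NetworkModel",
    "build_network",
    "electrode_positions",
    "assign_electrodes",
    "virtual_electrode_signal",
    "export_topology",
    "import_topology",
]


@dataclass
class NetworkModel:
    """A materialized network, ready for the simulation engine.

    Connectivity is stored in CSR-by-presynaptic-neuron form:
    edge k with ``indptr[j] <= k < indptr[j+1]`` runs j -> ``targets[k]``
    with dimensionless weight ``weights[k]`` (pre-scale-S) and axonal delay
    ``delays[k]`` ms.
    """

    config: NetworkConfig
    seed: int
    n_neurons: int
    indptr: np.ndarray  # (n+1,) int64
    targets: np.ndarray  # (n_edges,) int64
    weights: np.ndarray  # (n_edges,) float64, >= 0, unscaled by S
    delays: np.ndarray  # (n_edges,) float64 ms
    I_ext: np.ndarray  # (n,) float64 pA per-neuron constant drive
    positions: np.ndarray  # (n, 2) float64 µm
    elec_positions: np.ndarray  # (n_elec, 2) float64 µm
    elec_indptr: np.ndarray  # (n_elec+1,) int64
    elec_neurons: np.ndarray  # concatenated neuron indices per electrode

    @property
    def n_edges(self) -> int:
        return int(self.targets.size)

    def with_param(self, path: str, value) -> "NetworkModel":
        """Copy of the model with one scalar config parameter replaced.

        Random draws (topology, weights, delays, I_ext, positions) are kept:
        this is the primitive behind scheduled mid-run parameter switches.
        """
        return replace(self, config=replace_param(self.config, path, value))


def electrode_positions(layout: ElectrodeLayout, culture_size: float) -> np.ndarray:
    """Grid electrode centers (µm), centered on the square culture area."""
    xs = (np.arange(layout.n_cols) - (layout.n_cols - 1) / 2.0) * layout.pitch
    ys = (np.arange(layout.n_rows) - (layout.n_rows - 1) / 2.0) * layout.pitch
    gx, gy = np.meshgrid(xs, ys)
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    return pos + culture_size / 2.0


def assign_electrodes(positions: np.ndarray, elec_positions: np.ndarray,
                      capture_radius: float):
    """Map each electrode to the neurons within its capture radius.

    Returns CSR arrays (indptr, neuron_indices).  A neuron may be picked up
    by several electrodes; electrodes may be empty.
    """
    groups = []
    for e in range(elec_positions.shape[0]):
        d = np.linalg.norm(positions - elec_positions[e], axis=1)
        groups.append(np.flatnonzero(d <= capture_radius).astype(np.int64))
    indptr = np.zeros(len(groups) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([g.size for g in groups])
    neurons = (
        np.concatenate(groups) if indptr[-1] > 0 else np.empty(0, dtype=np.int64)
    )
    return indptr, neurons


def build_network(config: NetworkConfig, seed: int) -> NetworkModel:
    """Draw one network from the config: Bernoulli adjacency over ordered
    pairs (no self-connections), truncated-normal weights, uniform delays,
    per-neuron external drive, uniform 2-D placement, electrode assignment.

    The same ``(config, seed)`` always yields the identical model; separate
    child streams are used per ingredient so that e.g. changing the weight
    distribution leaves the adjacency untouched.
    """
    config.validate()
    top = config.topology
    syn = config.synapse
    het = config.heterogeneity
    n = top.n_neurons

    ss = np.random.SeedSequence(seed)
    r_adj, r_w, r_delay, r_iext, r_pos = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    # adjacency: Bernoulli(p) over ordered pairs, self-connections excluded
    mask = r_adj.random((n, n)) < top.connection_prob
    np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    order = np.lexsort((post, pre))
    pre, post = pre[order], post[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    indptr = np.cumsum(indptr)
    n_edges = pre.size

    if het.homogeneous:
        weights = np.full(n_edges, syn.w_mean)
        delays = np.full(n_edges, 0.5 * (syn.delay_min + syn.delay_max))
        I_ext = np.full(n, het.I_ext_mean)
    else:
        weights = np.maximum(r_w.normal(syn.w_mean, syn.w_sd, n_edges), 0.0)
        delays = r_delay.uniform(syn.delay_min, syn.delay_max, n_edges)
        I_ext = r_iext.normal(het.I_ext_mean, het.I_ext_sd, n)

    positions = r_pos.uniform(0.0, top.culture_size, (n, 2))
    elec_pos = electrode_positions(config.electrodes, top.culture_size)
    e_indptr, e_neurons = assign_electrodes(
        positions, elec_pos, config.electrodes.capture_radius
    )

    return NetworkModel(
        config=config,
        seed=seed,
        n_neurons=n,
        indptr=indptr,
        targets=post.astype(np.int64),
        weights=weights,
        delays=delays,
        I_ext=I_ext,
        positions=positions,
        elec_positions=elec_pos,
        elec_indptr=e_indptr,
        elec_neurons=e_neurons,
    )


def virtual_electrode_signal(v_traces: np.ndarray, fs_in: float,
                             elec_indptr: np.ndarray, elec_neurons: np.ndarray,
                             noise_sd: float, rng, fs_out: float = 10000.0,
                             v_rest: float = -65.0) -> np.ndarray:
    """Virtual-electrode transform of membrane-potential traces.

    Each channel is the mean deviation from rest (mV -> µV) of the neurons
    assigned to that electrode, decimated from ``fs_in`` to ``fs_out`` and
    with additive white measurement noise.  Electrodes with no assigned
    neuron record pure noise.  ``v_traces`` is (n_neurons, n_samples) mV.
    """
    stride = fs_in / fs_out
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    stride = int(round(stride))
    n_elec = elec_indptr.size - 1
    sub = v_traces[:, ::stride]
    out = np.zeros((n_elec, sub.shape[1]), dtype=np.float64)
    for e in range(n_elec):
        idx = elec_neurons[elec_indptr[e]:elec_indptr[e + 1]]
        if idx.size:
            out[e] = (sub[idx].mean(axis=0) - v_rest) * 1000.0  # mV -> µV
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, out.shape)
    return out


def export_topology(model: NetworkModel, edges_path, positions_path=None) -> None:
    """Write the edge list (pre, post, weight, delay_ms) and optionally the
    neuron positions as CSV."""
    pre = np.repeat(np.arange(model.n_neurons), np.diff(model.indptr))
    df = pd.DataFrame(
        {
            "pre": pre,
            "post": model.targets,
            "weight": model.weights,
            "delay_ms": model.delays,
        }
    )
    df.to_csv(edges_path, index=False)
    if positions_path is not None:
        pd.DataFrame(model.positions, columns=["x_um", "y_um"]).to_csv(
            positions_path, index=False
        )


def import_topology(edges_path):
    """Read an edge-list CSV back into CSR arrays.

    Returns (indptr, targets, weights, delays); the edge list must cover
    presynaptic indices 0..max contiguously (missing ones get no edges).
    """
    df = pd.read_csv(edges_path)
    n = int(max(df["pre"].max(), df["post"].max())) + 1 if len(df) else 0
    df = df.sort_values(["pre", "post"], kind="mergesort")
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, df["pre"].to_numpy() + 1, 1)
    indptr = np.cumsum(indptr)
    return (
        indptr,
        df["post"].to_numpy(dtype=np.int64),
        df["weight"].to_numpy(dtype=float),
        df["delay_ms"].to_numpy(dtype=float),
    )
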