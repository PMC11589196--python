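"""Synthetic MEA recordings with known ground truth, plus artifact IO.

The generator emulates the structure of a 12-electrode, 10 kHz extracellular
recording: Gaussian background noise, a biphasic spike waveform planted at
inhomogeneous-Poisson times, and burst envelopes built from Gaussian
sub-bumps so that network bursts and their fragments have exact, known
positions.  It exists so the analysis pipeline can be tested end-to-end
without a simulator; it is not a biophysical model.

Readers/writers cover the HDF5 recording container, a per-channel CSV
fallback, and the CSV feature-table / NB-annotation outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import h5py
import numpy as np
import pandas as pd

from .mea import FeatureTable, NBAnnotation
from .recording import Recording

__all__ = [
    "BurstPlan",
    "FixtureSpec",
    "GroundTruth",
    "spike_template",
    "generate_fixture",
    "write_recording",
    "read_recording",
    "write_recording_csv",
    "read_recording_csv",
    "write_feature_table",
    "write_nb_annotation",
]


@dataclass
class BurstPlan:
    """One planted network burst.

    The firing-rate envelope is a sum of Gaussian sub-bumps at
    ``center_s + offset`` with standard deviation ``width_s`` and relative
    amplitude ``rel_amp``; ``rate_hz`` scales the per-electrode peak rate of
    the largest sub-bump.
    """

    center_s: float
    width_s: float = 0.1  # sd of each Gaussian sub-bump
    rate_hz: float = 120.0  # per-electrode peak spike rate
    sub_bumps: List[Tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 1.0)]
    )  # (offset_s, relative amplitude)


@dataclass
class FixtureSpec:
    n_electrodes: int = 12
    fs: float = 10000.0
    duration: float = 30.0  # s
    noise_sd: float = 10.0  # µV
    spike_amplitude: float = 80.0  # µV (peak, in noise_sd multiples x 10 µV)
    spike_width_ms: float = 1.0
    bursts: List[BurstPlan] = field(default_factory=list)
    background_hz: float = 0.1  # per-electrode background spike rate
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact plants: per-electrode spike times, NB intervals, fragments."""

    spike_times: List[np.ndarray]  # per electrode, s
    nb_intervals: np.ndarray  # (n_nb, 2) s
    fragment_times: List[np.ndarray]  # per NB, sub-bump centers (s)

    @property
    def fragment_counts(self) -> np.ndarray:
        return np.array([f.size for f in self.fragment_times], dtype=int)


def spike_template(fs: float, amplitude: float, width_ms: float = 1.0
                   ) -> np.ndarray:
    """Biphasic cosine-windowed extracellular spike waveform.

    Negative-leading (amplitude = |negative peak|), ``width_ms`` total
    duration, zero mean outside its support.
    """
    n = max(4, int(round(width_ms * 1e-3 * fs)))
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    wave = -np.sin(2.0 * np.pi * t) * np.hanning(n)
    wave /= np.abs(wave).max()
    return amplitude * wave


def _envelope(spec: FixtureSpec, t: np.ndarray) -> Tuple[np.ndarray, list]:
    """Summed burst envelope (per-electrode rate, Hz) and per-burst bump info."""
    env = np.zeros_like(t)
    bump_centers = []
    for plan in spec.bursts:
        centers = []
        for off, rel in plan.sub_bumps:
            c = plan.center_s + off
            env += plan.rate_hz * rel * np.exp(
                -0.5 * ((t - c) / plan.width_s) ** 2
            )
            centers.append((c, rel))
        bump_centers.append(centers)
    return env, bump_centers


def _merge_intervals(intervals: np.ndarray) -> Tuple[np.ndarray, List[List[int]]]:
    """Merge overlapping [t0, t1] rows; also return member indices per merge."""
    if len(intervals) == 0:
        return np.empty((0, 2)), []
    order = np.argsort(intervals[:, 0])
    merged = [list(intervals[order[0]])]
    members = [[int(order[0])]]
    for k in order[1:]:
        t0, t1 = intervals[k]
        if t0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t1)
            members[-1].append(int(k))
        else:
            merged.append([t0, t1])
            members.append([int(k)])
    return np.asarray(merged), members


def generate_fixture(spec: FixtureSpec) -> Tuple[Recording, GroundTruth]:
    """Build a synthetic recording and its exact ground truth.

    Spike times are drawn per electrode from an inhomogeneous Poisson
    process (envelope + constant background) by thinning; the biphasic
    template is added at each spike onto Gaussian noise.  Overlapping burst
    plans are merged in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.fs))
    t_grid = np.arange(n_samples) / spec.fs
    env, bump_info = _envelope(spec, t_grid)
    lam = env + spec.background_hz
    lam_max = float(lam.max()) if n_samples else spec.background_hz

    template = spike_template(spec.fs, spec.spike_amplitude, spec.spike_width_ms)
    half = template.size

    voltage = rng.normal(0.0, spec.noise_sd, (spec.n_electrodes, n_samples))
    spike_times = []
    for _ch in range(spec.n_electrodes):
        # homogeneous Poisson at lam_max, thinned by lam(t)/lam_max
        n_cand = rng.poisson(lam_max * spec.duration)
        cand = np.sort(rng.uniform(0.0, spec.duration, n_cand))
        idx = np.minimum((cand * spec.fs).astype(int), n_samples - 1)
        keep = rng.uniform(0.0, 1.0, n_cand) < lam[idx] / lam_max
        st = cand[keep]
        spike_times.append(st)
        for s in st:
            i0 = int(round(s * spec.fs))
            i1 = min(i0 + half, n_samples)
            voltage[_ch, i0:i1] += template[: i1 - i0]

    # ground-truth NB intervals: ±3 sd around each sub-bump, merged per spec
    raw = []
    frag_centers = []
    for plan, centers in zip(spec.bursts, bump_info):
        cs = [c for c, _ in centers]
        lo = min(cs) - 3.0 * plan.width_s
        hi = max(cs) + 3.0 * plan.width_s
        raw.append([lo, hi])
        frag_centers.append(np.asarray(sorted(cs)))
    raw = np.asarray(raw).reshape(-1, 2)
    merged, members = _merge_intervals(raw)
    fragments = [
        np.sort(np.concatenate([frag_centers[i] for i in mem]))
        for mem in members
    ]

    rec = Recording(voltage=voltage, fs=spec.fs)
    gt = GroundTruth(
        spike_times=spike_times, nb_intervals=merged, fragment_times=fragments
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Recording container IO

def write_recording(rec: Recording, path) -> None:
    """HDF5 layout: /recording/voltage (channels x samples, µV), /recording/fs,
    channel ids and well id as attributes.  Lossless round trip."""
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        g.create_dataset("voltage", data=rec.voltage)
        g.create_dataset("fs", data=float(rec.fs))
        g.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        g.attrs["well_id"] = rec.well_id


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "recording" not in f:
            raise ValueError("malformed container: missing group 'recording'")
        g = f["recording"]
        for name in ("voltage", "fs"):
            if name not in g:
                raise ValueError(f"malformed container: missing field '{name}'")
        return Recording(
            voltage=np.asarray(g["voltage"]),
            fs=float(g["fs"][()]),
            channel_ids=[str(c) for c in g.attrs.get("channel_ids", [])],
            well_id=str(g.attrs.get("well_id", "well0")),
        )


def write_recording_csv(rec: Recording, path) -> None:
    """CSV fallback for small fixtures: t_s column plus one column per channel."""
    df = pd.DataFrame(rec.voltage.T, columns=rec.channel_ids)
    df.insert(0, "t_s", rec.time())
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path) -> Recording:
    df = pd.read_csv(path)
    if "t_s" not in df.columns:
        raise ValueError("malformed CSV recording: missing column 't_s'")
    t = df["t_s"].to_numpy()
    if t.size < 2:
        raise ValueError("malformed CSV recording: need >= 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    chans = [c for c in df.columns if c != "t_s"]
    return Recording(
        voltage=df[chans].to_numpy().T, fs=round(fs, 6), channel_ids=chans
    )


def write_feature_table(features, path) -> None:
    """One CSV row per well/recording; accepts one FeatureTable or a list."""
    if isinstance(features, FeatureTable):
        features = [features]
    df = pd.concat([f.to_dataframe() for f in features], ignore_index=True)
    df.to_csv(path, index=False)


def write_nb_annotation(ann: NBAnnotation, path) -> None:
    """CSV with one row per NB (header always written)."""
    ann.to_dataframe().to_csv(path, index=False)
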