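"""Recording-to-features MEA analysis pipeline.

Applied identically to simulated (virtual-electrode) and experimental
recordings: band-pass filtering, threshold spike detection, binned network
firing rate, Gaussian smoothing, two-threshold network-burst (NB)
detection with an electrode-participation criterion, fragment (intra-NB
peak) detection, and the four summary features

* ``fragments_per_nb`` — mean number of firing-rate peaks per NB,
* ``NBR`` — NBs per minute,
* ``NBD`` — mean NB duration (s),
* ``CV_IBI`` — coefficient of variation of inter-burst (start-to-start)
  intervals.

All thresholds are *relative* (to channel RMS or to the maximum smoothed
rate), making every downstream quantity invariant under rescaling of the
voltage traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .recording import Recording

__all__ = [
    "AnalysisConfig",
    "NBAnnotation",
    "FeatureTable",
    "bandpass_filter",
    "detect_spikes",
    "network_firing_rate",
    "smooth_rate",
    "detect_nbs",
    "detect_fragments",
    "compute_features",
    "analyze_recording",
]


@dataclass
class AnalysisConfig:
    """Pipeline thresholds; defaults follow the standard protocol."""

    f_low: float = 100.0  # Hz band-pass lower edge
    f_high: float = 3500.0  # Hz upper edge
    filter_order: int = 5  # Butterworth order
    spike_thresh_rms: float = 4.0  # threshold in channel-RMS multiples
    dead_time_ms: float = 1.0  # per-channel refractory for detection
    bin_ms: float = 25.0  # network-rate bin width
    kernel_sd_bins: float = 2.0  # Gaussian smoothing sd (bins)
    nb_start_frac: float = 0.25  # NB start threshold, fraction of max rate
    nb_stop_frac: float = 0.01  # NB stop threshold
    frag_height_frac: float = 1.0 / 16.0  # fragment peak min height
    frag_prom_frac: float = 0.1  # fragment peak min prominence
    active_hz: float = 0.02  # electrode counts as active above this rate
    min_active_frac: float = 0.3  # fraction of active electrodes in an NB
    persist_ms: float = 50.0  # threshold persistence for start/stop
    cv_ddof: int = 0  # population (0) vs sample (1) sd for CV_IBI


@dataclass
class NBAnnotation:
    """Detected NBs, their fragments, and the smoothed rate they came from."""

    starts: np.ndarray  # (n_nb,) s
    stops: np.ndarray  # (n_nb,) s
    fragment_times: List[np.ndarray]  # per NB, peak times (s)
    truncated: np.ndarray  # (n_nb,) bool — NB touches a recording edge
    rate: np.ndarray  # smoothed network rate (spikes/bin)
    bin_edges: np.ndarray  # (n_bins+1,) s

    @property
    def n_nbs(self) -> int:
        return int(self.starts.size)

    @property
    def fragment_counts(self) -> np.ndarray:
        return np.array([ft.size for ft in self.fragment_times], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nb_id": np.arange(self.n_nbs),
                "start_s": self.starts,
                "stop_s": self.stops,
                "n_fragments": self.fragment_counts,
                "truncated": self.truncated,
                "fragment_times": [
                    ";".join(f"{t:.4f}" for t in ft) for ft in self.fragment_times
                ],
            }
        )


@dataclass
class FeatureTable:
    """Per-recording summary features.

    ``cv_ibi`` and ``nbd`` are NaN when undefined (fewer than 3 NBs for the
    CV; no complete NB for the duration).
    """

    fragments_per_nb: float
    nbr: float  # NBs / min
    nbd: float  # s
    cv_ibi: float
    n_nbs: int
    active_electrode_count: int
    well_id: str = "well0"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": [self.well_id],
                "n_nbs": [self.n_nbs],
                "nbr_per_min": [self.nbr],
                "nbd_s": [self.nbd],
                "cv_ibi": [self.cv_ibi],
                "fragments_per_nb": [self.fragments_per_nb],
                "active_electrodes": [self.active_electrode_count],
            }
        )


def bandpass_filter(rec: Recording, config: Optional[AnalysisConfig] = None) -> Recording:
    """Zero-phase Butterworth band-pass (default 5th order, 100-3,500 Hz)."""
    config = config or AnalysisConfig()
    if rec.fs < 2.0 * config.f_high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {config.f_high} Hz band edge"
        )
    sos = signal.butter(
        config.filter_order,
        [config.f_low, config.f_high],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, rec.voltage, axis=1)
    return Recording(
        voltage=filtered, fs=rec.fs, channel_ids=list(rec.channel_ids),
        well_id=rec.well_id,
    )


def detect_spikes(rec: Recording, config: Optional[AnalysisConfig] = None
                  ) -> List[np.ndarray]:
    """Per-channel spike times (s): |signal| above ``spike_thresh_rms`` times
    the channel RMS, one event per crossing with a dead time."""
    config = config or AnalysisConfig()
    dead = max(1, int(round(config.dead_time_ms * 1e-3 * rec.fs)))
    out = []
    for ch in range(rec.n_channels):
        v = rec.voltage[ch]
        rms = np.sqrt(np.mean(v**2))
        if rms == 0:
            out.append(np.empty(0))
            continue
        above = np.abs(v) > config.spike_thresh_rms * rms
        idx = np.flatnonzero(above)
        if idx.size == 0:
            out.append(np.empty(0))
            continue
        keep = [idx[0]]
        for i in idx[1:]:
            if i - keep[-1] >= dead:
                keep.append(i)
        out.append(np.asarray(keep) / rec.fs)
    return out


def network_firing_rate(spikes_per_channel: List[np.ndarray], duration: float,
                        config: Optional[AnalysisConfig] = None
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Spike counts across all electrodes in fixed bins (default 25 ms).

    Returns (counts, bin_edges_s); the counts sum to the total spike count.
    """
    config = config or AnalysisConfig()
    bin_s = config.bin_ms * 1e-3
    n_bins = max(1, int(np.ceil(duration / bin_s - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for st in spikes_per_channel:
        if st.size:
            counts += np.histogram(st, bins=edges)[0]
    return counts, edges


def smooth_rate(counts: np.ndarray, config: Optional[AnalysisConfig] = None
                ) -> np.ndarray:
    """Gaussian smoothing (unit-sum kernel, reflective boundaries)."""
    config = config or AnalysisConfig()
    return gaussian_filter1d(counts.astype(float), config.kernel_sd_bins,
                             mode="reflect")


def detect_nbs(smoothed: np.ndarray, bin_edges: np.ndarray,
               spikes_per_channel: List[np.ndarray], duration: float,
               config: Optional[AnalysisConfig] = None):
    """Two-threshold NB detection on the smoothed network rate.

    A burst starts when the rate holds above ``max/4`` for the persistence
    window, extends backward/forward to the ``max/100`` crossings (the stop
    threshold must also hold for the persistence window to end the burst),
    and is kept only if at least ``min_active_frac`` of the active
    electrodes (mean rate above ``active_hz``) fire within it.  Overlapping
    candidates are merged.

    Returns (intervals, truncated, n_active): intervals is an (n_nb, 2)
    array of [start_s, stop_s], truncated marks NBs clipped by the
    recording edges.
    """
    config = config or AnalysisConfig()
    bin_s = bin_edges[1] - bin_edges[0]
    persist = max(1, int(np.ceil(config.persist_ms * 1e-3 / bin_s - 1e-9)))
    n_bins = smoothed.size

    rates = np.array([st.size / duration for st in spikes_per_channel])
    active = rates > config.active_hz
    n_active = int(active.sum())

    peak = smoothed.max() if n_bins else 0.0
    if peak <= 0 or n_active == 0:
        return np.empty((0, 2)), np.empty(0, dtype=bool), n_active

    start_th = config.nb_start_frac * peak
    stop_th = config.nb_stop_frac * peak
    above_start = smoothed >= start_th
    below_stop = smoothed < stop_th

    intervals = []
    i = 0
    while i < n_bins:
        # find the next sustained start-threshold crossing
        trig = -1
        run = 0
        j = i
        while j < n_bins:
            run = run + 1 if above_start[j] else 0
            if run == persist:
                trig = j - persist + 1
                break
            j += 1
        if trig < 0:
            break
        # extend backward to the last bin below the stop threshold
        b = trig
        while b > 0 and not below_stop[b - 1]:
            b -= 1
        # extend forward: burst ends at the first sustained sub-stop run
        e = trig
        run = 0
        end = n_bins  # exclusive
        while e < n_bins:
            run = run + 1 if below_stop[e] else 0
            if run == persist:
                end = e - persist + 1
                break
            e += 1
        intervals.append((b, end))
        i = end + 1

    # merge overlaps (backward extension can reach into the previous burst)
    merged = []
    for b, e in intervals:
        if merged and b <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([b, e])

    kept = []
    truncated = []
    need = config.min_active_frac * n_active
    for b, e in merged:
        t0 = bin_edges[b]
        t1 = bin_edges[min(e, n_bins)]
        firing = sum(
            1
            for ch, st in enumerate(spikes_per_channel)
            if active[ch] and st.size and np.any((st >= t0) & (st < t1))
        )
        if firing >= need:
            kept.append((t0, t1))
            truncated.append(b == 0 or e >= n_bins)
    return (
        np.asarray(kept).reshape(-1, 2),
        np.asarray(truncated, dtype=bool),
        n_active,
    )


def detect_fragments(smoothed: np.ndarray, bin_edges: np.ndarray,
                     intervals: np.ndarray,
                     config: Optional[AnalysisConfig] = None
                     ) -> List[np.ndarray]:
    """Fragment peaks within each NB: local maxima of the smoothed rate with
    minimum height ``max/16`` and topographic prominence ``max/10``.

    Peak times are bin centers (s); an NB may contain zero qualifying peaks.
    """
    config = config or AnalysisConfig()
    peak = smoothed.max() if smoothed.size else 0.0
    if peak <= 0:
        return [np.empty(0) for _ in range(len(intervals))]
    locs, _props = signal.find_peaks(
        smoothed,
        height=config.frag_height_frac * peak,
        prominence=config.frag_prom_frac * peak,
    )
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    peak_times = centers[locs]
    out = []
    for t0, t1 in intervals:
        out.append(peak_times[(peak_times >= t0) & (peak_times < t1)])
    return out


def compute_features(intervals: np.ndarray, fragment_times: List[np.ndarray],
                     truncated: np.ndarray, duration: float,
                     n_active: int = 0, well_id: str = "well0",
                     config: Optional[AnalysisConfig] = None) -> FeatureTable:
    """Summary features from detected NBs.

    NBR counts every NB; NBD and fragments/NB use only NBs not clipped by
    the recording edges; CV_IBI uses start-to-start intervals and is NaN
    with fewer than 3 NBs.
    """
    config = config or AnalysisConfig()
    n_nbs = len(intervals)
    duration_min = duration / 60.0
    nbr = n_nbs / duration_min if duration_min > 0 else 0.0
    if n_nbs == 0:
        return FeatureTable(
            fragments_per_nb=np.nan, nbr=0.0, nbd=np.nan, cv_ibi=np.nan,
            n_nbs=0, active_electrode_count=n_active, well_id=well_id,
        )
    complete = ~np.asarray(truncated, dtype=bool)
    if complete.any():
        durs = intervals[complete, 1] - intervals[complete, 0]
        nbd = float(np.mean(durs))
        n_frag = sum(fragment_times[i].size for i in np.flatnonzero(complete))
        fragments_per_nb = n_frag / int(complete.sum())
    else:
        nbd = np.nan
        fragments_per_nb = np.nan
    if n_nbs >= 3:
        ibis = np.diff(intervals[:, 0])
        mu = ibis.mean()
        cv = float(ibis.std(ddof=config.cv_ddof) / mu) if mu > 0 else np.nan
    else:
        cv = np.nan
    return FeatureTable(
        fragments_per_nb=float(fragments_per_nb),
        nbr=float(nbr),
        nbd=nbd,
        cv_ibi=cv,
        n_nbs=n_nbs,
        active_electrode_count=n_active,
        well_id=well_id,
    )


def analyze_recording(rec: Recording, config: Optional[AnalysisConfig] = None
                      ) -> Tuple[NBAnnotation, FeatureTable]:
    """Run the full pipeline on a recording.

    filter -> spike detection -> binned rate -> smoothing -> NB detection ->
    fragment detection -> features.
    """
    config = config or AnalysisConfig()
    filt = bandpass_filter(rec, config)
    spikes = detect_spikes(filt, config)
    counts, edges = network_firing_rate(spikes, rec.duration, config)
    smoothed = smooth_rate(counts, config)
    intervals, truncated, n_active = detect_nbs(
        smoothed, edges, spikes, rec.duration, config
    )
    fragments = detect_fragments(smoothed, edges, intervals, config)
    features = compute_features(
        intervals, fragments, truncated, rec.duration, n_active,
        well_id=rec.well_id, config=config,
    )
    ann = NBAnnotation(
        starts=intervals[:, 0] if len(intervals) else np.empty(0),
        stops=intervals[:, 1] if len(intervals) else np.empty(0),
        fragment_times=fragments,
        truncated=truncated,
        rate=smoothed,
        bin_edges=edges,
    )
    return ann, features
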