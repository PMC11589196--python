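"""Analysis pipeline: filtering, spike/NB/fragment detection, features."""

import numpy as np
import pytest

from fragburst.mea import (
    bandpass_filter,
    compute_features,
    detect_fragments,
    detect_nbs,
    detect_spikes,
    network_firing_rate,
    smooth_rate,
)
from fragburst.recording import Recording


def _sine_recording(freq, fs=10000.0, duration=2.0, amp=100.0):
    t = np.arange(int(duration * fs)) / fs
    return Recording(voltage=amp * np.sin(2 * np.pi * freq * t)[None, :], fs=fs)


class TestFilter:
    def test_dc_rejected(self):
        rec = Recording(voltage=np.full((2, 20000), 50.0), fs=10000.0)
        out = bandpass_filter(rec)
        assert np.max(np.abs(out.voltage)) < 1e-6

    def test_passband_preserved(self):
        out = bandpass_filter(_sine_recording(1000.0))
        mid = out.voltage[0, 5000:-5000]
        assert np.max(np.abs(mid)) == pytest.approx(100.0, rel=0.05)

    def test_stopband_attenuated(self):
        out = bandpass_filter(_sine_recording(10.0))
        mid = out.voltage[0, 5000:-5000]
        # > 20 dB attenuation
        assert np.max(np.abs(mid)) < 100.0 / 10.0

    def test_low_sampling_rate_rejected(self):
        rec = Recording(voltage=np.zeros((1, 1000)), fs=5000.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec)


class TestSpikeDetection:
    def test_zero_channel_has_no_spikes(self):
        rec = Recording(voltage=np.zeros((3, 10000)), fs=10000.0)
        spikes = detect_spikes(rec)
        assert all(s.size == 0 for s in spikes)

    def test_gaussian_noise_false_positive_rate(self):
        # beyond 4 sigma two-sided: rate < 1 Hz per channel over 5 minutes
        rng = np.random.default_rng(0)
        fs, dur = 10000.0, 300.0
        rec = Recording(voltage=rng.normal(0, 10, (1, int(fs * dur))), fs=fs)
        spikes = detect_spikes(rec)
        assert spikes[0].size / dur < 1.0

    def test_planted_spikes_recovered(self):
        rng = np.random.default_rng(1)
        fs = 10000.0
        v = rng.normal(0, 10, int(fs * 20.0))
        truth = (np.arange(100) * 0.2 + 0.05)
        for t in truth:
            v[int(t * fs)] -= 100.0  # 10x noise RMS
        rec = Recording(voltage=v[None, :], fs=fs)
        det = detect_spikes(rec)[0]
        matched = sum(np.any(np.abs(det - t) <= 1e-3) for t in truth)
        assert matched >= 99
        # exactly one detection per planted spike (no doubles in the window)
        for t in truth:
            assert np.sum(np.abs(det - t) <= 1e-3) <= 1
        # residual false positives are bare noise crossings: < 1 Hz
        extra = sum(not np.any(np.abs(truth - d) <= 1e-3) for d in det)
        assert extra / 20.0 < 1.0


class TestRate:
    def test_counts_conserve_spikes(self):
        spikes = [np.array([0.1, 0.5, 0.9]), np.array([0.2]), np.empty(0)]
        counts, edges = network_firing_rate(spikes, duration=1.0)
        assert counts.sum() == 4
        assert edges[1] - edges[0] == pytest.approx(0.025)

    def test_uniform_spikes_one_per_bin(self):
        spikes = [np.arange(40) * 0.025 + 0.0125]
        counts, _ = network_firing_rate(spikes, duration=1.0)
        assert np.all(counts == 1)

    def test_smoothing_preserves_mass_and_constants(self):
        c = np.full(100, 3.0)
        assert np.allclose(smooth_rate(c), 3.0)
        impulse = np.zeros(101)
        impulse[50] = 1.0
        sm = smooth_rate(impulse)
        assert sm.sum() == pytest.approx(1.0, abs=1e-9)
        assert sm[50] == sm.max()


def _bump_trace(n_bins=1200, center=600, sd_bins=20, peak=40.0):
    b = np.arange(n_bins)
    return peak * np.exp(-0.5 * ((b - center) / sd_bins) ** 2)


def _spikes_on_channels(n_channels, t0, t1, rate=50.0, duration=30.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_channels):
        n = rng.poisson(rate * (t1 - t0))
        st = np.sort(rng.uniform(t0, t1, n))
        out.append(st)
    return out


class TestNBDetection:
    def test_flat_trace_no_nbs(self):
        edges = np.arange(101) * 0.025
        intervals, truncated, n_active = detect_nbs(
            np.zeros(100), edges, [np.empty(0)] * 12, duration=2.5
        )
        assert len(intervals) == 0

    def test_single_gaussian_bump_detected_at_stop_threshold_crossings(self):
        n_bins, center, sd = 1200, 600, 20
        trace = _bump_trace(n_bins, center, sd)
        edges = np.arange(n_bins + 1) * 0.025
        duration = n_bins * 0.025
        spikes = _spikes_on_channels(
            12, edges[center - 3 * sd], edges[center + 3 * sd],
            duration=duration,
        )
        intervals, truncated, n_active = detect_nbs(trace, edges, spikes, duration)
        assert len(intervals) == 1
        assert n_active == 12
        # analytic max/100 crossings of the Gaussian: center ± sd*sqrt(2 ln 100)
        half_width_bins = sd * np.sqrt(2 * np.log(100.0))
        t_lo = (center - half_width_bins) * 0.025
        t_hi = (center + half_width_bins) * 0.025
        assert intervals[0][0] == pytest.approx(t_lo, abs=0.026)
        assert intervals[0][1] == pytest.approx(t_hi, abs=0.06)
        assert not truncated[0]

    def test_electrode_participation_criterion(self):
        n_bins, center, sd = 1200, 600, 20
        trace = _bump_trace(n_bins, center, sd)
        edges = np.arange(n_bins + 1) * 0.025
        duration = n_bins * 0.025
        # 12 active electrodes overall, but only 2 fire inside the bump
        inside = _spikes_on_channels(2, 14.0, 16.0, duration=duration)
        outside = _spikes_on_channels(10, 0.0, 5.0, duration=duration, seed=1)
        intervals, _, n_active = detect_nbs(
            trace, edges, inside + outside, duration
        )
        assert n_active == 12
        assert len(intervals) == 0


class TestFragments:
    def test_single_bump_single_fragment(self):
        n_bins = 1200
        trace = _bump_trace(n_bins)
        edges = np.arange(n_bins + 1) * 0.025
        frags = detect_fragments(trace, edges, np.array([[10.0, 20.0]]))
        assert frags[0].size == 1

    def test_two_bumps_with_deep_trough_are_two_fragments(self):
        n_bins = 1200
        trace = _bump_trace(n_bins, 500, 15, peak=40.0) + _bump_trace(
            n_bins, 700, 15, peak=20.0
        )
        edges = np.arange(n_bins + 1) * 0.025
        frags = detect_fragments(trace, edges, np.array([[10.0, 20.0]]))
        assert frags[0].size == 2

    def test_prominence_filter_with_brute_force_oracle(self):
        # small secondary ripple: prominence max/20 < max/10 -> rejected
        n_bins = 1200
        trace = _bump_trace(n_bins, 600, 30, peak=40.0)
        ripple = _bump_trace(n_bins, 700, 5, peak=40.0 / 20.0)
        trace2 = trace + ripple
        edges = np.arange(n_bins + 1) * 0.025

        def prominence_oracle(y, i):
            # water-level: drop to the highest minimum separating i from
            # any higher peak (or the trace edge)
            left = y[: i + 1]
            right = y[i:]
            higher_l = np.flatnonzero(left > y[i])
            higher_r = np.flatnonzero(right > y[i])
            lmin = left[higher_l[-1]:].min() if higher_l.size else left.min()
            rmin = right[: higher_r[0] + 1].min() if higher_r.size else right.min()
            return y[i] - max(lmin, rmin)

        # the ripple creates a local max near bin 700
        seg = slice(690, 715)
        i_rip = 690 + int(np.argmax(trace2[seg]))
        assert prominence_oracle(trace2, i_rip) < trace2.max() / 10.0
        frags = detect_fragments(trace2, edges, np.array([[10.0, 20.0]]))
        assert frags[0].size == 1


class TestFeatures:
    def test_nbr_counts_all_nbs(self):
        intervals = np.array([[i * 30.0, i * 30.0 + 1.0] for i in range(10)])
        frags = [np.array([i * 30.0 + 0.5]) for i in range(10)]
        truncated = np.zeros(10, dtype=bool)
        f = compute_features(intervals, frags, truncated, duration=300.0)
        assert f.nbr == pytest.approx(2.0)
        assert f.nbd == pytest.approx(1.0)
        assert f.cv_ibi == pytest.approx(0.0)
        assert f.fragments_per_nb == pytest.approx(1.0)

    def test_cv_ibi_hand_computed(self):
        intervals = np.array([[0.0, 1.0], [10.0, 11.0], [30.0, 31.0]])
        frags = [np.empty(0)] * 3
        f = compute_features(
            intervals, frags, np.zeros(3, dtype=bool), duration=60.0
        )
        # IBIs {10, 20}: population sd 5, mean 15
        assert f.cv_ibi == pytest.approx(5.0 / 15.0)

    def test_no_nbs_flags_undefined(self):
        f = compute_features(np.empty((0, 2)), [], np.empty(0, bool), 60.0)
        assert f.nbr == 0.0
        assert np.isnan(f.nbd) and np.isnan(f.cv_ibi)

    def test_cv_undefined_below_three_nbs(self):
        intervals = np.array([[0.0, 1.0], [10.0, 11.0]])
        f = compute_features(
            intervals, [np.empty(0)] * 2, np.zeros(2, bool), 60.0
        )
        assert np.isnan(f.cv_ibi)

    def test_truncated_nbs_counted_for_nbr_only(self):
        intervals = np.array([[0.0, 5.0], [10.0, 11.0]])
        frags = [np.array([1.0, 2.0, 3.0]), np.array([10.5])]
        truncated = np.array([True, False])
        f = compute_features(intervals, frags, truncated, duration=60.0)
        assert f.nbr == pytest.approx(2.0)
        assert f.nbd == pytest.approx(1.0)
        assert f.fragments_per_nb == pytest.approx(1.0)
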