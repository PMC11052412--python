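"""High-pass response, Katz FD, window screening and clean-segment extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hemotrace import denoise as dn
from hemotrace import qrs, synth

FS = 240.0


def _sine(freq, duration=60.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestHighpass:
    def test_dc_rejection(self):
        out = dn.highpass_ap(np.full(int(30 * FS), 100.0), FS)
        assert np.max(np.abs(out[int(5 * FS) : -int(5 * FS)])) < 1e-6

    def test_passband_gain_near_unity(self):
        x, _ = _sine(1.2)
        out = dn.highpass_ap(x, FS)
        core = slice(int(10 * FS), -int(10 * FS))
        gain = np.max(np.abs(out[core]))
        assert gain == pytest.approx(1.0, rel=0.01)

    def test_drift_attenuated_pulse_preserved(self):
        drift, _ = _sine(0.05, amp=30.0)
        pulse, _ = _sine(1.2, amp=20.0)
        out = dn.highpass_ap(drift + pulse, FS)
        core = slice(int(10 * FS), -int(10 * FS))
        resid_drift = dn.highpass_ap(drift, FS)[core]
        # >= 20 dB attenuation of the drift; pulse amplitude preserved
        assert np.max(np.abs(resid_drift)) < 30.0 / 10
        assert np.max(np.abs(out[core])) == pytest.approx(20.0, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dn.highpass_ap(np.zeros(1000), 100.0, cutoff=60.0)


class TestKatzFD:
    @pytest.mark.parametrize("slope", [0.01, 1.0, -250.0])
    def test_ramp_is_exactly_one(self, slope):
        x = slope * np.arange(100, dtype=float)
        assert dn.katz_fd(x) == pytest.approx(1.0, abs=1e-12)

    def test_high_frequency_content_raises_fd(self):
        t = np.arange(500) / 500
        for seed in range(20):
            phase = np.random.default_rng(seed).uniform(0, 2 * np.pi)
            base = np.sin(2 * np.pi * 2 * t + phase)
            assert dn.katz_fd(base + 0.1 * np.sin(2 * np.pi * 50 * t)) > dn.katz_fd(base)

    def test_white_noise_rougher_than_pulse(self):
        wins = 0
        n = 400
        pulse = synth._beat_template(np.linspace(0, 0.8, n), 0.8, 120, 80)
        for seed in range(100):
            noise = np.random.default_rng(seed).standard_normal(n)
            wins += dn.katz_fd(noise) > dn.katz_fd(pulse)
        assert wins > 50

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dn.katz_fd(np.full(50, 7.0))

    @given(hst.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_fd_at_least_one(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert dn.katz_fd(x) >= 1.0


class TestWindowing:
    def test_window_count_with_overlap(self):
        ap = np.zeros(int(60 * FS))
        wins = dn.window_signal(ap, cycle_length=1.0, sampling_rate=FS, hp=ap)
        assert len(wins) == 19  # floor((60-6)/3) + 1

    def test_exactly_one_window(self):
        ap = np.zeros(int(6 * FS))
        assert len(dn.window_signal(ap, 1.0, FS, hp=ap)) == 1

    def test_signal_shorter_than_window(self):
        ap = np.zeros(int(5 * FS))
        with pytest.warns(UserWarning, match="shorter"):
            assert dn.window_signal(ap, 1.0, FS, hp=ap) == []

    def test_segment_split_remainder_to_last(self):
        w = dn.APWindow(0, 601, np.arange(601.0), np.arange(601.0))
        segs = dn._segments(w.samples)
        assert [len(s) for s in segs] == [200, 200, 201]


class TestClassification:
    def test_constant_window_stats(self):
        w = dn.APWindow(0, 600, np.full(600, 90.0), np.zeros(600))
        stats = dn.window_stats(w)
        assert stats.seg_means == (90.0, 90.0, 90.0)
        assert stats.sds == (0.0, 0.0, 0.0, 0.0)

    def test_flatline_discarded_by_sd_floor(self):
        w = dn.APWindow(0, 600, np.full(600, 90.0), np.zeros(600))
        assert not dn.classify_window(dn.window_stats(w), dn.DenoiseThresholds())

    def test_extreme_pressure_discarded(self):
        ap = np.full(600, 300.0) + np.random.default_rng(0).normal(0, 5, 600)
        w = dn.APWindow(0, 600, ap, ap - ap.mean())
        assert not dn.classify_window(dn.window_stats(w), dn.DenoiseThresholds())

    def test_clean_pulse_kept(self, clean_record):
        peaks = qrs.detect_r_peaks(clean_record.ecg, clean_record.sampling_rate)
        cyc = qrs.heart_cycle_length(peaks)
        hp = dn.highpass_ap(clean_record.ap, clean_record.sampling_rate)
        wins = dn.window_signal(clean_record.ap, cyc, clean_record.sampling_rate, hp=hp)
        thr = dn.DenoiseThresholds()
        assert all(dn.classify_window(dn.window_stats(w), thr) for w in wins)

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="lower bound"):
            dn.DenoiseThresholds(fd_range=(1.2, 1.0))


class TestCleanSegments:
    def test_clean_record_mostly_kept(self, clean_record):
        segs = dn.clean_segments(clean_record)
        assert segs.kept_mask(len(clean_record.ap)).mean() >= 0.95
        assert not segs.poor_quality

    def test_noise_mostly_excluded(self, noisy_record):
        segs = dn.clean_segments(noisy_record)
        mask = segs.kept_mask(len(noisy_record.ap))
        overlap = (mask & noisy_record.truth_noise_mask).sum()
        assert overlap / noisy_record.truth_noise_mask.sum() <= 0.2

    def test_ranges_sorted_disjoint(self, noisy_record):
        segs = dn.clean_segments(noisy_record)
        for (a0, a1), (b0, b1) in zip(segs.ranges, segs.ranges[1:]):
            assert a0 < a1 <= b0 < b1

    def test_deterministic(self, noisy_record):
        a = dn.clean_segments(noisy_record)
        b = dn.clean_segments(noisy_record)
        assert a.ranges == b.ranges

    def test_all_flatline_flagged_poor_quality(self, clean_record):
        rec = synth.SignalRecord(
            subject_id="flat",
            time=clean_record.time,
            ap=np.full_like(clean_record.ap, 90.0),
            ecg=clean_record.ecg,
            sampling_rate=clean_record.sampling_rate,
            truth_r_peaks=clean_record.truth_r_peaks,
            truth_noise_mask=np.ones_like(clean_record.truth_noise_mask),
            truth_beat_bounds=clean_record.truth_beat_bounds,
        )
        segs = dn.clean_segments(rec)
        assert segs.poor_quality and segs.ranges == []
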