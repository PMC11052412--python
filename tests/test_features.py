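"""Beat segmentation, per-beat feature formulas, aggregation, pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hemotrace import features as ft
from hemotrace import qrs, synth
from hemotrace.experiments import random_beats
from hemotrace.pipeline import extract_cohort_features

FS = 240.0


def _template_beat(period=0.8, sbp=120.0, dbp=80.0, fs=FS, **kw):
    n = int(round(period * fs))
    t = np.arange(n + 1) / fs
    p = synth._beat_template(t, period, sbp, dbp, **kw)
    return ft.BeatWaveform(p=p, t=t, sampling_rate=fs)


class TestSegmentBeats:
    def test_interior_beats_of_ten_second_minute_rate(self):
        rec = synth.synth_signal(
            synth.SignalSpec(duration=10.0, heart_rate=60), seed=4
        )
        beats, rejected = ft.segment_beats(rec.ap, rec.truth_r_peaks, rec.sampling_rate)
        assert len(beats) == 9  # first/last partial cycles dropped
        assert rejected == 0

    def test_segment_shorter_than_cycle_is_empty(self):
        beats, _ = ft.segment_beats(np.full(50, 90.0), np.array([10]), FS)
        assert beats == []

    def test_bounds_match_generator_truth(self, clean_record):
        rec = clean_record
        beats, _ = ft.segment_beats(rec.ap, rec.truth_r_peaks, rec.sampling_rate)
        truth = rec.truth_beat_bounds
        for b in beats:
            lo, hi = b.start_index, b.start_index + len(b.p)
            overlaps = np.minimum(hi, truth[:, 1]) - np.maximum(lo, truth[:, 0])
            j = np.argmax(overlaps)
            inter = max(0, overlaps[j])
            union = max(hi, truth[j, 1]) - min(lo, truth[j, 0])
            assert inter / union >= 0.9


class TestBeatFeatureFormulas:
    def test_pressure_and_timing_formulas(self):
        v = ft.beat_feature_vector(_template_beat(period=0.8, sbp=120, dbp=80))
        assert v["DBP"] == pytest.approx(80, abs=0.5)
        assert v["SBP"] == pytest.approx(120, abs=0.5)
        assert v["PP"] == pytest.approx(40, abs=1.0)
        assert v["MAP"] == pytest.approx((2 * 80 + 120) / 3, abs=0.7)
        assert v["HB"] == pytest.approx(60 / 0.8, abs=0.5)
        assert v["AT"] < v["DT"]

    def test_symmetric_triangle_has_zero_skew_and_equal_halves(self):
        n = 101
        p = 80 + 40 * np.concatenate([np.linspace(0, 1, n // 2 + 1), np.linspace(1, 0, n // 2 + 1)[1:]])
        t = np.arange(n) / FS
        v = ft.beat_feature_vector(ft.BeatWaveform(p=p, t=t, sampling_rate=FS))
        assert v["SK"] == pytest.approx(0.0, abs=0.005)
        assert v["AT"] == pytest.approx(v["DT"], abs=1e-12)
        assert v["UA"] == pytest.approx(v["DA"], rel=1e-9)

    def test_constant_beat_rejected(self):
        beat = ft.BeatWaveform(p=np.full(120, 100.0), t=np.arange(120) / FS, sampling_rate=FS)
        assert not beat.is_valid()
        with pytest.raises(ValueError, match="constant"):
            ft.beat_feature_vector(beat)

    def test_spectral_entropy_limits(self):
        # single PSD bin -> 0 bits; two equal bins -> 1 bit
        n, fs = 256, 256.0
        t = np.arange(n) / fs
        one = ft.BeatWaveform(p=np.sin(2 * np.pi * 8 * t), t=t, sampling_rate=fs)
        two = ft.BeatWaveform(
            p=np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 23 * t), t=t, sampling_rate=fs
        )
        assert ft.beat_feature_vector(one)["SE"] == pytest.approx(0.0, abs=1e-9)
        assert ft.beat_feature_vector(two)["SE"] == pytest.approx(1.0, abs=1e-9)

    def test_identities_on_random_beats(self):
        for beat in random_beats(50, seed=3):
            v = ft.beat_feature_vector(beat)
            assert v["PP"] == pytest.approx(v["SBP"] - v["DBP"], abs=1e-12)
            assert v["AOC"] == pytest.approx(v["UA"] + v["DA"], abs=1e-9)
            assert v["AT"] + v["DT"] == pytest.approx(beat.duration, abs=1e-12)
            assert v["KU"] >= v["SK"] ** 2 + 1 - 1e-9
            assert v["FD"] >= 1.0


class TestOverallTime:
    def test_span(self):
        assert ft.overall_time(np.linspace(0, 600, 1000)) == pytest.approx(600)

    def test_gaps_do_not_matter(self):
        t = np.concatenate([np.arange(0, 10, 0.1), np.arange(50, 60, 0.1)])
        assert ft.overall_time(t) == pytest.approx(59.9)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ft.overall_time(np.array([]))


class TestTrimmedMean:
    def test_drops_two_from_each_tail(self):
        assert ft.trimmed_mean(np.arange(1, 11), trim=0.2) == pytest.approx(5.5)

    def test_single_value_untouched(self):
        assert ft.trimmed_mean(np.array([5.0]), trim=0.4) == 5.0

    def test_outlier_excluded(self):
        assert ft.trimmed_mean(np.array([0, 0, 0, 0, 1000.0]), trim=0.2) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ft.trimmed_mean(np.array([]))

    @given(hst.lists(hst.floats(-1e6, 1e6), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_bounded(self, values):
        x = np.asarray(values)
        tm = ft.trimmed_mean(x)
        shuffled = np.random.default_rng(0).permutation(x)
        assert ft.trimmed_mean(shuffled) == pytest.approx(tm, rel=1e-9, abs=1e-9)
        assert min(values) - 1e-9 <= tm <= max(values) + 1e-9


class TestPruneCorrelated:
    def test_exact_duplicate_pruned(self, rng):
        a = rng.standard_normal(200)
        X = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.standard_normal(200)})
        retained = ft.prune_correlated(X, order=["A", "B", "C"])
        assert retained == ["A", "C"]

    def test_independent_features_all_retained(self, rng):
        X = pd.DataFrame(rng.standard_normal((1000, 8)), columns=list("abcdefgh"))
        assert ft.prune_correlated(X, order=list("abcdefgh")) == list("abcdefgh")

    def test_pulse_pressure_or_parent_removed(self, small_features):
        retained = ft.prune_correlated(small_features[ft.FEATURE_ORDER])
        assert not {"PP", "SBP", "DBP"} <= set(retained)
        assert ("SBP" in retained) or ("DBP" in retained)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"A": rng.standard_normal(50), "B": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            retained = ft.prune_correlated(X, order=["A", "B"])
        assert retained == ["A"]


class TestSubjectLevelRecovery:
    def test_generator_parameters_recovered_within_two_percent(self):
        cspec = synth.CohortSpec(
            n_subjects=20, prevalence=0.15, seed=21,
            signal_spec=synth.SignalSpec(duration=20.0, artifact_fraction=0.0),
        )
        cohort = synth.synth_cohort(cspec)
        table, excluded = extract_cohort_features(cohort)
        assert excluded == []
        merged = table.merge(cohort.signal_truth, on="subject_id")
        assert np.allclose(merged["SBP"], merged["true_sbp"], rtol=0.02)
        assert np.allclose(merged["DBP"], merged["true_dbp"], rtol=0.02)
        assert np.allclose(merged["HB"], merged["true_heart_rate"], rtol=0.02)

    def test_aggregation_trims_and_counts(self, small_features):
        assert (small_features["n_beats_used"] > 5).all()
        assert (small_features["SBP"] > small_features["DBP"]).all()
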