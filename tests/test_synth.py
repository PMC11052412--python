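"""Generator contracts: determinism, ground truth, planted effects."""

import numpy as np
import pandas as pd
import pytest

from hemotrace import stats, synth


class TestSignalSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            ({"sampling_rate": 50}, "sampling_rate"),
            ({"sbp": 80, "dbp": 90}, "20 < dbp < sbp < 300"),
            ({"sbp": 310, "dbp": 80}, "20 < dbp < sbp < 300"),
            ({"artifact_fraction": 0.95}, "artifact_fraction"),
            ({"at_fraction": 0.6}, "at_fraction"),
        ],
    )
    def test_invalid_spec_names_violated_bound(self, kwargs, fragment):
        with pytest.raises(ValueError, match=fragment):
            synth.SignalSpec(**kwargs)

    def test_cohort_spec_bounds(self):
        with pytest.raises(ValueError, match="n_subjects"):
            synth.CohortSpec(n_subjects=10)
        with pytest.raises(ValueError, match=">= 2"):
            synth.CohortSpec(n_subjects=30, prevalence=0.01)


class TestSynthSignal:
    def test_beat_count_matches_rate(self):
        rec = synth.synth_signal(
            synth.SignalSpec(duration=10.0, heart_rate=60), seed=0
        )
        assert len(rec.truth_r_peaks) == 10

    def test_no_artifacts_means_empty_mask(self, clean_record):
        assert not clean_record.truth_noise_mask.any()

    def test_clean_beats_span_dbp_to_sbp(self, clean_record):
        for lo, hi in clean_record.truth_beat_bounds[:10]:
            seg = clean_record.ap[lo:hi]
            assert seg.max() == pytest.approx(120, abs=6)
            assert seg.min() == pytest.approx(80, abs=5)

    def test_identical_seed_identical_record(self):
        spec = synth.SignalSpec(duration=8.0, artifact_fraction=0.2)
        a = synth.synth_signal(spec, seed=42)
        b = synth.synth_signal(spec, seed=42)
        assert np.array_equal(a.ap, b.ap)
        assert np.array_equal(a.ecg, b.ecg)
        assert np.array_equal(a.truth_noise_mask, b.truth_noise_mask)

    def test_artifact_fraction_realised(self):
        rec = synth.synth_signal(
            synth.SignalSpec(duration=60.0, artifact_fraction=0.3), seed=3
        )
        assert rec.truth_noise_mask.mean() == pytest.approx(0.3, abs=0.05)

    def test_each_beat_bound_contains_one_r_peak(self, noisy_record):
        peaks = noisy_record.truth_r_peaks
        for lo, hi in noisy_record.truth_beat_bounds:
            assert np.sum((peaks >= lo) & (peaks < hi)) == 1

    def test_ecg_has_one_qrs_per_beat(self, clean_record):
        # QRS spikes dominate the ECG: one prominent max per beat bound
        for lo, hi in clean_record.truth_beat_bounds[:5]:
            seg = clean_record.ecg[lo:hi]
            assert seg.max() > 0.8


class TestSynthCohort:
    def test_death_count_matches_prevalence(self):
        cspec = synth.CohortSpec(n_subjects=605, prevalence=0.0843, seed=1)
        cohort = synth.synth_cohort(cspec, generate_signals=False)
        assert cohort.clinical["outcome"].sum() == 51

    def test_null_generator_has_null_effects(self):
        cspec = synth.CohortSpec(
            n_subjects=2000, prevalence=0.2, seed=9,
            effect_sizes={k: 0.0 for k in synth.DEFAULT_EFFECT_SIZES},
        )
        cohort = synth.synth_cohort(cspec, generate_signals=False)
        clin = cohort.clinical
        y = clin["outcome"].to_numpy()
        d = stats.cohens_d_from_samples(
            clin.loc[y == 0, "age"], clin.loc[y == 1, "age"]
        )
        assert abs(d) < 0.15
        t = stats.ContingencyTable2x2(
            a=int(((clin.renal_dysfunction == 1) & (y == 0)).sum()),
            b=int(((clin.renal_dysfunction == 1) & (y == 1)).sum()),
            c=int(((clin.renal_dysfunction == 0) & (y == 0)).sum()),
            d=int(((clin.renal_dysfunction == 0) & (y == 1)).sum()),
        )
        assert abs(stats.phi_coefficient(t)) < 0.06

    def test_planted_age_effect_recovered_unbiased(self):
        # mean recovered pooled-SD d over replicates brackets the target
        ds = []
        for s in range(150):
            cohort = synth.synth_cohort(
                synth.CohortSpec(n_subjects=2000, prevalence=0.1, seed=100 + s),
                generate_signals=False,
            )
            clin = cohort.clinical
            y = clin["outcome"].to_numpy()
            ds.append(
                stats.cohens_d_from_samples(
                    clin.loc[y == 0, "age"], clin.loc[y == 1, "age"]
                )
            )
        mean_d = np.mean(ds)
        sem = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(mean_d - 0.57) < max(2 * sem, 0.02)

    def test_planted_binary_effect_recovered(self):
        phis = []
        for s in range(100):
            cohort = synth.synth_cohort(
                synth.CohortSpec(n_subjects=2000, prevalence=0.1, seed=500 + s),
                generate_signals=False,
            )
            clin = cohort.clinical
            y = clin["outcome"].to_numpy()
            rd = clin["renal_dysfunction"].to_numpy()
            t = stats.ContingencyTable2x2(
                a=int(((rd == 1) & (y == 0)).sum()),
                b=int(((rd == 1) & (y == 1)).sum()),
                c=int(((rd == 0) & (y == 0)).sum()),
                d=int(((rd == 0) & (y == 1)).sum()),
            )
            phis.append(abs(stats.phi_coefficient(t)))
        sem = np.std(phis, ddof=1) / np.sqrt(len(phis))
        assert abs(np.mean(phis) - 0.26) < max(2 * sem, 0.02)

    def test_infeasible_binary_effect_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth.plant_binary_rates(prevalence=0.05, exposure=0.008, phi=0.9)

    def test_nonsurvivors_draw_lower_pressures_faster_rate(self):
        cohort = synth.synth_cohort(
            synth.CohortSpec(n_subjects=2000, prevalence=0.3, seed=2),
            generate_signals=False,
        )
        t = cohort.signal_truth
        died, surv = t[t.outcome == 1], t[t.outcome == 0]
        assert died.true_sbp.mean() < surv.true_sbp.mean()
        assert died.true_dbp.mean() < surv.true_dbp.mean()
        assert died.true_heart_rate.mean() > surv.true_heart_rate.mean()

    def test_cohort_determinism(self):
        cspec = synth.CohortSpec(n_subjects=25, prevalence=0.2, seed=77)
        a = synth.synth_cohort(cspec)
        b = synth.synth_cohort(cspec)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert np.array_equal(a.records[3].ap, b.records[3].ap)
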