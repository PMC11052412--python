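"""Reusable study drivers: every headline quantity computed in one place.

These functions are shared by the numbered analysis scripts, the acceptance
machinery and the test suite, so the same code path produces every reported
number. Each takes an explicit seed and returns plain numbers/frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import denoise as dn
from . import ensemble as ens
from . import features as ft
from . import published
from . import qrs
from . import select as sel
from . import stats as st
from .pipeline import COMBINED_COVARIATES, extract_cohort_features, make_selector
from .synth import CohortSpec, SignalSpec, _beat_template, synth_cohort, synth_signal

#: cohort-scale study conditions: published cohort size and prevalence,
#: desk-scale 30 s recordings with a 10% artifact burden
COHORT_N = 605
COHORT_PREVALENCE = 0.0843
COHORT_SIGNAL = dict(duration=30.0, artifact_fraction=0.1)


def phi_recomputation() -> pd.DataFrame:
    """|φ| recomputed from the published 2×2 counts vs the printed values."""
    rows = []
    for name, table in published.BINARY_FACTORS.items():
        rows.append(
            {
                "factor": name,
                "phi_computed": round(abs(st.phi_coefficient(table)), 2),
                "phi_printed": published.PRINTED_PHI[name],
                "chi2_p": st.chi_square_2x2(table)[1],
            }
        )
    return pd.DataFrame(rows)


def mortality_percent() -> float:
    """1-year mortality prevalence (%) from the published counts."""
    m = published.mortality_table()
    return round(100.0 * m["n_died"] / m["n_total"], 2)


def qrs_accuracy_study(
    rates: tuple[float, ...] = (40, 60, 80, 100, 120, 140),
    duration: float = 30.0,
    sampling_rate: float = 240.0,
    seed: int = 0,
    tol_samples: int = 2,
) -> dict[str, float]:
    """Peak sensitivity and positive predictivity on artifact-free ECG."""
    tp = fp = fn = 0
    for i, rate in enumerate(rates):
        spec = SignalSpec(sampling_rate=sampling_rate, duration=duration, heart_rate=rate)
        rec = synth_signal(spec, seed=seed + i)
        det = qrs.detect_r_peaks(rec.ecg, rec.sampling_rate).indices
        truth = rec.truth_r_peaks
        if len(det):
            matched = np.abs(det[:, None] - truth[None, :]).min(axis=1) <= tol_samples
        else:
            matched = np.zeros(0, dtype=bool)
        tp += int(matched.sum())
        fp += int((~matched).sum())
        hit = (
            np.abs(truth[:, None] - det[None, :]).min(axis=1) <= tol_samples
            if len(det)
            else np.zeros(len(truth), dtype=bool)
        )
        fn += int((~hit).sum())
    return {
        "sensitivity": tp / (tp + fn),
        "ppv": tp / (tp + fp),
        "n_beats": tp + fn,
    }


def denoise_accuracy_study(
    n_seeds: int = 10,
    artifact_fraction: float = 0.3,
    duration: float = 60.0,
    seed: int = 0,
) -> dict[str, float]:
    """Window-level noise classification vs truth masks, and noise exclusion."""
    thr = dn.DenoiseThresholds()
    accs, excls = [], []
    for s in range(n_seeds):
        spec = SignalSpec(duration=duration, artifact_fraction=artifact_fraction)
        rec = synth_signal(spec, seed=seed + s)
        peaks = qrs.detect_r_peaks(rec.ecg, rec.sampling_rate)
        cyc = qrs.heart_cycle_length(peaks)
        hp = dn.highpass_ap(rec.ap, rec.sampling_rate)
        wins = dn.window_signal(rec.ap, cyc, rec.sampling_rate, hp=hp)
        correct = 0
        for w in wins:
            keep = dn.classify_window(dn.window_stats(w), thr)
            noisy = rec.truth_noise_mask[w.start : w.end].mean() > 0.5
            correct += keep == (not noisy)
        accs.append(correct / len(wins))
        segs = dn.clean_segments(rec, thr, peaks=peaks)
        mask = segs.kept_mask(len(rec.ap))
        excls.append(1 - (mask & rec.truth_noise_mask).sum() / rec.truth_noise_mask.sum())
    return {
        "window_accuracy": float(np.mean(accs)),
        "noise_excluded": float(np.mean(excls)),
        "n_seeds": n_seeds,
    }


def random_beats(n_beats: int, seed: int = 0, sampling_rate: float = 240.0):
    """Random single pulses spanning realistic morphology ranges."""
    rng = np.random.default_rng(seed)
    beats = []
    while len(beats) < n_beats:
        period = rng.uniform(0.45, 1.4)
        sbp = rng.uniform(95, 185)
        dbp = rng.uniform(50, sbp - 25)
        n = int(round(period * sampling_rate))
        tau = np.arange(n + 1) / sampling_rate
        p = _beat_template(
            tau, period, sbp, dbp,
            at_fraction=rng.uniform(0.22, 0.40), decay=rng.uniform(2.0, 4.0),
        )
        p = p + 0.3 * rng.standard_normal(len(p))
        beat = ft.BeatWaveform(p=p, t=tau, sampling_rate=sampling_rate)
        if beat.is_valid():
            beats.append(beat)
    return beats


def feature_identity_study(n_beats: int = 1000, seed: int = 0) -> dict[str, float]:
    """Worst-case violation of the per-beat identities over random pulses."""
    errs = {"pp": 0.0, "aoc": 0.0, "duration": 0.0}
    for beat in random_beats(n_beats, seed=seed):
        v = ft.beat_feature_vector(beat)
        errs["pp"] = max(errs["pp"], abs(v["PP"] - (v["SBP"] - v["DBP"])))
        errs["aoc"] = max(errs["aoc"], abs(v["AOC"] - (v["UA"] + v["DA"])))
        errs["duration"] = max(errs["duration"], abs(v["AT"] + v["DT"] - beat.duration))
    return errs


def katz_study(n_seeds: int = 100, n_samples: int = 400) -> dict[str, float]:
    """Ramp exactness and monotone response to added high-frequency content."""
    ramp = dn.katz_fd(np.linspace(0.0, 5.0, n_samples))
    t = np.arange(n_samples) / n_samples
    increases = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(s)
        base = np.sin(2 * np.pi * 3 * t + rng.uniform(0, 2 * np.pi))
        rough = base + 0.10 * np.sin(2 * np.pi * 40 * t + rng.uniform(0, 2 * np.pi))
        increases += dn.katz_fd(rough) > dn.katz_fd(base)
    return {"ramp_fd": ramp, "monotone_fraction": increases / n_seeds}


def planted_selection_data(
    n: int = 400,
    d: float = 1.5,
    n_noise: int = 7,
    prevalence: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Two discriminative features (shift d) among ``n_noise`` pure-noise ones."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < prevalence).astype(int)
    while y.sum() < 2 or y.sum() > n - 2:
        y = (rng.random(n) < prevalence).astype(int)
    cols = {}
    planted = ["planted_1", "planted_2"]
    for name in planted:
        cols[name] = rng.standard_normal(n) + d * y
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), y, planted


def selection_recovery_study(
    method: str = "LBFS",
    n_runs: int = 20,
    n: int = 400,
    d: float = 1.5,
    n_reps: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of runs in which both planted features land in the top five."""
    fn = sel.lbfs if method == "LBFS" else sel.pbfs
    hits = 0
    for run in range(n_runs):
        X, y, planted = planted_selection_data(n=n, d=d, seed=seed + run)
        tally = fn(X, y, n_reps=n_reps, seed=seed + 10_000 + run)
        hits += set(planted) <= set(tally.top5)
    return {"recovery_fraction": hits / n_runs, "n_runs": n_runs}


def ensemble_partition_check(n_minority: int = 51, n_majority: int = 554, seed: int = 0) -> dict:
    """Subdataset bookkeeping at published class sizes."""
    y = np.array([1] * n_minority + [0] * n_majority)
    idx = np.arange(len(y))
    subsets = ens.balanced_subdatasets(idx, y, seed=seed)
    majority_used = np.concatenate([s.majority for s in subsets])
    return {
        "n_subdatasets": len(subsets),
        "last_majority_size": len(subsets[-1].majority),
        "majority_once": len(majority_used) == n_majority
        and len(np.unique(majority_used)) == n_majority,
        "minority_in_all": all(len(s.minority) == n_minority for s in subsets),
    }


def _cohort_features(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    cspec = CohortSpec(
        n_subjects=COHORT_N,
        prevalence=COHORT_PREVALENCE,
        seed=seed,
        signal_spec=SignalSpec(**COHORT_SIGNAL),
    )
    cohort = synth_cohort(cspec)
    table, _ = extract_cohort_features(cohort)
    merged = table.merge(cohort.clinical.drop(columns=["outcome"]), on="subject_id")
    return table, merged


def direction_study(
    n_seeds: int = 10,
    seed: int = 0,
    classifier: str = "LDA",
    selector_method: str = "LBFS",
    selector_reps: int = 50,
) -> pd.DataFrame:
    """Cohort-scale AP-only vs combined (AP + clinical covariates) models.

    One full signal-level cohort per seed; per-fold feature selection; the
    balanced-subdataset ensemble inside stratified 10-fold CV.
    """
    rows = []
    for s in range(n_seeds):
        table, merged = _cohort_features(seed + s)
        retained = ft.prune_correlated(table[ft.FEATURE_ORDER])
        X = table[retained].reset_index(drop=True)
        y = table["outcome"].to_numpy(dtype=int)
        extra = merged[COMBINED_COVARIATES].reset_index(drop=True)
        selector = make_selector(selector_method, selector_reps)
        ap = ens.run_cv_experiment(X, y, classifier=classifier, seed=seed + s, selector=selector)
        comb = ens.run_cv_experiment(
            X, y, classifier=classifier, seed=seed + s, selector=selector, extra_features=extra
        )
        rows.append(
            {
                "seed": seed + s,
                "ap_auc": ap.auc,
                "combined_auc": comb.auc,
                "ap_specificity": ap.specificity,
                "combined_specificity": comb.specificity,
                "ap_sensitivity": ap.sensitivity,
                "combined_sensitivity": comb.sensitivity,
                "ap_precision": ap.precision,
                "combined_precision": comb.precision,
            }
        )
    return pd.DataFrame(rows)


def permutation_null_study(
    n_shuffles: int = 10,
    seed: int = 0,
    classifier: str = "LDA",
) -> dict[str, float]:
    """Mean CV AUC after label shuffling (features from one real cohort)."""
    table, _ = _cohort_features(seed)
    retained = ft.prune_correlated(table[ft.FEATURE_ORDER])
    X = table[retained].reset_index(drop=True)
    y = table["outcome"].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    aucs = []
    for s in range(n_shuffles):
        y_perm = rng.permutation(y)
        rep = ens.run_cv_experiment(X, y_perm, classifier=classifier, seed=seed + s)
        aucs.append(rep.auc)
    return {"mean_auc": float(np.mean(aucs)), "n_shuffles": n_shuffles}
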