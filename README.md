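# hemotrace

Intra-procedural arterial-pressure (AP) traces recorded during primary
percutaneous coronary intervention (PPCI) carry prognostic information that
routine risk scores ignore. `hemotrace` implements a complete, tested pipeline
that turns such traces — together with basic clinical covariates — into
1-year mortality risk models for STEMI patients:

1. **QRS detection** (Pan–Tompkins: band-pass 5–15 Hz → derivative → squaring
   → 150 ms moving integration → adaptive thresholding) supplies each
   subject's heart-cycle length.
2. **AP denoising**: the trace is tiled with 6-heart-cycle windows at 50%
   overlap; each window is screened on ten characteristics — three segment
   means, four standard deviations, and three segment **Katz fractal
   dimensions** D = log₁₀(n) / (log₁₀(n) + log₁₀(d/L)) computed on the
   0.4 Hz high-pass output — against physiological thresholds. Kept windows
   merge into clean segments.
3. **Beat features**: clean segments are split into trough-to-trough pulses;
   18 features per beat/subject (HB, DBP, SBP, PP, MAP = (2·DBP+SBP)/3, OT,
   AT, DT, AOC = ∫p dt, UA, DA, AR = DA/UA, MS = max p′, Katz FD, skewness,
   kurtosis, spectral entropy of the unit-sum PSD, average power), aggregated
   with a 20% trimmed mean and pruned at pairwise |r| > 0.7.
4. **Feature selection**: two 1000-repetition down-sampling procedures —
   LBFS (per-feature 1-D LDA ranked by validation sensitivity) and PBFS
   (mean |Pearson r| between each feature and the first four PCA score
   vectors) — each tally a top-5.
5. **Imbalance-aware evaluation**: inside stratified 10-fold CV, each
   training fold's majority class is partitioned across ceil(majority/minority)
   balanced subdatasets; one KNN/LDA/SVM model per subdataset; test scores are
   averaged (test folds keep the cohort's ~8.4% prevalence — precision is low
   by design). Metrics: accuracy, specificity, sensitivity, precision, AUC.

Because the original catheter-lab recordings are not publicly deposited, the
package includes a first-class **synthetic cohort generator** that emulates
the published cohort's structure (605 subjects, 8.43% one-year mortality,
age d ≈ 0.57, renal-dysfunction φ ≈ 0.26, lower SBP/DBP and higher heart
rate in non-survivors) with per-sample ground truth for every pipeline stage.

## Worked example

```python
from hemotrace import synth, qrs, denoise, features, pipeline

spec = synth.SignalSpec(duration=30, heart_rate=75, sbp=120, dbp=80,
                        artifact_fraction=0.3)
rec = synth.synth_signal(spec, seed=7)

peaks = qrs.detect_r_peaks(rec.ecg, rec.sampling_rate)
print(f"{len(peaks)} R peaks, cycle {qrs.heart_cycle_length(peaks):.3f} s")

segs = denoise.clean_segments(rec)
kept = segs.kept_mask(len(rec.ap)).mean()
print(f"kept {kept:.0%} of samples in {len(segs.ranges)} clean segments")

row = pipeline.extract_record_features(rec)
print(f"SBP {row['SBP']:.1f}  DBP {row['DBP']:.1f}  HB {row['HB']:.1f}  "
      f"FD {row['FD']:.3f}  ({row['n_beats_used']} beats)")
```

prints

```
38 R peaks, cycle 0.792 s
kept 55% of samples in 2 clean segments
SBP 119.9  DBP 79.1  HB 75.2  FD 1.034  (19 beats)
```

— 38 beats detected at 75 bpm over 30 s; with a 30% artifact burden roughly
half of the trace survives screening; the trimmed-mean beat features
recover the generator's 120/80 mmHg pressures and heart rate, and the
per-beat Katz FD sits just above 1 as clean pulses should.

The numbered drivers under `analysis/` run the full study and write their
tables to `results/`: `01` recomputes the published cohort effect sizes from
printed counts, `02` simulates and summarizes the cohort-scale synthetic
population, `03`–`04` validate denoising/QRS and the feature identities,
`05` runs pruning plus both selectors, and `06` evaluates the AP-only and
combined (AP + age/renal dysfunction/dialysis/EST) mortality models. The same
stages are available as a CLI (`hemotrace synth|detect|denoise|extract|select|
evaluate|stats|all --config cfg.yaml --seed 1 --out DIR`).

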