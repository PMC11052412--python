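# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `hemotrace`. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The problem

STEMI patients treated with primary PCI still face ~8% one-year mortality.
The hypothesis embodied in this pipeline is that the morphology of the
arterial-pressure (AP) wave recorded through the catheter during the
procedure — pulse amplitude, upstroke timing, waveform complexity — carries
prognostic information beyond standard clinical covariates. The pipeline
therefore (i) cleans the AP trace, (ii) reduces each subject to a vector of
beat-morphology features, (iii) selects a small stable feature subset under
resampling, and (iv) evaluates classifiers under severe class imbalance
without discarding or fabricating data.

## Signal processing

**QRS detection.** Classic Pan–Tompkins with 5–15 Hz second-order Butterworth
band-pass (zero-phase), derivative, squaring, 150 ms moving-window
integration, and adaptive thresholding (running signal/noise peak estimates,
threshold = noise + 0.25·(signal − noise), 200 ms refractory). Integration
peaks are refined to the band-passed ECG maximum within ±75 ms. Thresholds
derive from the signal's own amplitudes, so detection is invariant under
positive rescaling. Heart-cycle length is the **median** inter-peak interval,
computed once per subject — the median tolerates occasional missed/extra
beats, and a single per-subject value keeps the window size stable.

**Denoising.** Windows span six heart cycles with 50% overlap; the trailing
remainder is dropped rather than padded (a partial window would bias its
segment statistics). Each window yields ten characteristics; the split of
responsibilities is a documented choice where the procedure is ambiguous:
segment means and the four SDs are computed on the **raw** AP window (their
thresholds are absolute pressures in mmHg), while the three segment Katz FDs
are computed on the **0.4 Hz high-pass** output (4th-order zero-phase
Butterworth; order is our choice), where drift is removed and residual
broadband noise dominates the polyline length. Default screens — segment
means ∈ [20, 250] mmHg, SDs ∈ [1, 60] mmHg, FD ∈ [1.0, 1.10] — encode that
pressures outside 20–250 mmHg are non-physiological, near-zero SD means
flatline, and clean pressure pulses evaluate to a Katz FD barely above 1
(about 1.03–1.06 on the generator's clean windows) while corrupted windows
jump well past 1.10. All three ranges are config-overridable and global
across subjects. A window is kept only if *all ten* characteristics pass.
Kept windows are merged into maximal disjoint half-open index ranges on the
original signal; a subject with zero kept windows is flagged poor-quality and
excluded, mirroring the exclusion of poor-quality recordings from analysis.
Feature extraction afterwards uses the **raw** AP inside kept ranges, since
the pressure features are absolute mmHg quantities.

**Katz fractal dimension.** D = log₁₀(n)/(log₁₀(n) + log₁₀(d/L)) on the
unit-index polyline (L = Σ√(1 + Δy²), d = max distance from the first
vertex). A straight ramp gives exactly 1. Constant series raise an error
rather than returning 1: a flatline must not masquerade as a clean simple
signal — the SD floor and this error jointly guarantee flatlines are
discarded.

## Beat features

Beats are delimited trough-to-trough: near each R peak the diastolic foot is
the AP minimum in an asymmetric window (5% of the RR interval before R to
30% after — the pressure foot follows the R wave). Beats must last 0.25–2 s,
be non-constant, and contain exactly one systolic peak (prominence ≥ 25% of
the beat's range); failures are rejected and counted. Formulas follow the
feature table in the README; numerically: trapezoidal integration on the
sample grid, derivatives by central differences, population moments for
skewness/kurtosis (kurtosis is *not* excess), PSD by periodogram of the
mean-removed beat. Spectral entropy normalizes the PSD to unit sum before
−Σq·log₂q — unnormalized entropy would not be amplitude-invariant; average
power is Σ PSD / n on the same periodogram. The MAP formula is the standard
clinical (2·DBP + SBP)/3. Per-subject aggregation uses a 20% trimmed mean
*per tail* (drop ⌊0.2·n⌋ smallest and largest, mean the rest); OT — the
recording span — passes through untrimmed.

**Correlation pruning.** Features are visited in the canonical table order;
one is retained only if |Pearson r| ≤ 0.7 with every feature already
retained. This greedy keep-the-earlier rule is deterministic; the procedure
that produced the original nine-feature set is not fully specified, so only
the rule, not the exact end-set, is contractual. Constant columns are
dropped with a warning. Whether OT belongs in the correlation matrix is
unspecified in the source description; it is included here.

## Feature selection

Both selectors down-sample the majority class to the minority size each
repetition (minority subjects are never dropped) and tally top-5 membership
over the repetitions (1000 by default).

**LBFS.** Per repetition: stratified 70/30 split; per feature a 1-D LDA with
equal priors and shared within-class variance — the boundary is the midpoint
of the class means, with orientation toward the "died" mean; features are
ranked by validation *sensitivity* (recall of the non-survivor class, the
clinically costly error).

**PBFS.** Per repetition: z-score the features, PCA, take the first four
component score vectors, score each feature by the mean |Pearson r| between
its column and the four score vectors, tally the five largest. Labels enter
only through down-sampling. No inner 70/30 split is used — the procedure
description contains none. Note a structural property: a feature's squared
correlations with orthogonal score vectors sum to ≤ 1, so the score rewards
features correlated with *several* retained components; a feature that only
drives one component caps its mean near 0.25. PBFS consequently cannot
recover a pure mean-shift planted among independent equal-variance features
(that is LBFS's job); its tests assert what it does guarantee — identical
scores for identical columns, and isolated noise never outranking
shared-structure features.

**Tie-breaking.** Within a repetition, score ties are broken *randomly* from
the repetition's seeded generator. A fixed-order tie-break would
systematically favour early features whenever scores are discrete (validation
sensitivities take few values at small n), visibly biasing the all-noise
tally. Aggregated top-5 ranking breaks count ties by the canonical feature
order, so everything is reproducible under the master seed.

## Imbalance-aware evaluation

Stratified 10-fold CV preserves the ~8.4% prevalence in every test fold —
test folds are never balanced, which is why precision is low (~0.15–0.25)
even for good models. Within a training fold the majority class is shuffled
and partitioned into ceil(majority/minority) chunks of minority size (the
last chunk holds the remainder); each balanced subdataset = all minority
subjects + one chunk. Every majority subject is used exactly once, every
minority subject n times. One model per subdataset; the ensemble score is
the unweighted mean of member scores (scores, not votes, so ROC curves are
well defined); the decision threshold is 0.5. Classifier defaults (the
source specifies none): KNN k=5 Euclidean, LDA with equal priors, linear SVM
C=1 with Platt-calibrated scores — all on features standardized with
training statistics. Feature selection runs *inside* each training fold by
default (no test leakage); a fixed-global mode exists behind a flag and the
report records which was used. Per-fold metrics are averaged across folds;
ROC curves are averaged vertically on a common FPR grid.

## Cohort statistics

Continuous covariates: Mann–Whitney U (exact null distribution when both
groups ≤ 8 without ties, else normal approximation with tie correction) and
Cohen's d with (n−1)-weighted pooled SD. Binary covariates: Pearson χ²
without continuity correction — the uncorrected statistic reproduces the
published stroke/TIA p ≈ 0.001 and the printed |φ| set, and satisfies
χ² = n·φ² exactly; a Yates-corrected mode exists behind a flag. Effect sizes
are reported as |values| to two decimals. Two printed values do not
reconcile with their own counts and are recorded, not "fixed": the male row
(prints 0.13, recomputes to 0.12) and the age d (prints 0.57; recomputing
from the rounded printed group summaries gives ≈ 0.61).

## The synthetic cohort

The generator defines the study conditions; its defaults are fixed once.

*Signals.* 240 Hz sampling (the acquisition system's rate is unpublished;
this is a flagged assumption), 30 s per subject at cohort scale (a desk-scale
span giving ~25–40 beats, ample for a stable 20% trimmed mean; single-signal
demos use 60 s). Beats are an asymmetric template: half-cosine upstroke over
30% of the cycle, exponential diastolic decay (rate 3/DT) back to DBP, so
AT < DT as real pulses have. Per-beat jitter: SBP ±1.5, DBP ±1.0 mmHg,
period ±2%; additive 0.3 mmHg measurement noise. Between subjects, the
upstroke fraction (SD 0.025) and decay rate (SD 0.4) vary — real patients
differ in waveform shape, and without this the timing/complexity features
would be deterministic functions of heart rate. The ECG is a Gaussian-bump
P-QRS-T train with one QRS per beat — sufficient for Pan–Tompkins, not a
physiological ECG model. Artifacts come as one sustained episode of
back-to-back contiguous blocks (lengths uniform 2–10 s; kinds: impulsive
spikes, flatline, baseline wander + broadband noise), mirroring the
prolonged disturbance of catheter manipulation; ground truth (noise mask,
R peaks, beat bounds) is stored alongside.

*Cohort.* n = 605, prevalence 8.43% (deaths fixed at round(prevalence·n);
which subjects die is random). Survivor hemodynamics: SBP ~ N(125, 15),
DBP regressed on SBP (slope 0.29, residual SD 6.7, mean 80), HR ~ N(76, 11);
non-survivors are shifted −10 mmHg SBP, −6 mmHg DBP (total), +8 bpm — the
directions reported for post-STEMI mortality, at magnitudes comparable to
the published Table-2 effect sizes. Clinical covariates plant the published
effects (age d = 0.57, RD φ = 0.26, dialysis φ = 0.24, EST d = −0.46, …);
binary effects are solved analytically from (prevalence, exposure, φ) and
rejected if infeasible. The *default* effect map clips binary φ to the
feasible range for the requested prevalence (a 0.8% exposure cannot carry
φ = 0.24 at 20% prevalence); explicitly supplied maps are validated
strictly.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: no Windkessel/ODE hemodynamics, dicrotic notches,
arrhythmias, respiratory modulation, or drift in clean segments; artifacts
are stylized; covariates are conditionally independent given outcome; the
link between clinical covariates and waveform morphology is limited to the
planted group shifts. Model AUCs on this cohort validate the *machinery*
(no leakage, correct ensemble accounting, sensible direction of effects),
not the clinical effect size of real AP morphology.

## Problem sizes and determinism

Cohort-scale studies use 10 independent seeds of the full 605-subject
signal-level cohort; selector recovery studies use 20 runs at n = 400 with
200 resampling repetitions; per-fold selection inside CV uses 50
repetitions. These desk-scale sizes keep every study reproducible in minutes
while leaving the estimators' Monte-Carlo error well below the margins being
tested. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical spec + seed yields byte-identical
records, tables, and reports.

## Known limitations

- The denoising thresholds are global; per-subject adaptation might help
  records whose baseline pressure sits near the screen boundaries.
- The beat delimiter assumes R peaks are available and reasonably accurate;
  severe ECG corruption would propagate into beat segmentation.
- The SVM's Platt calibration on small balanced subdatasets (~10–100
  subjects) is noisy; LDA is the most stable of the three classifiers at
  these sizes.
- `mann_whitney_u` switches from the exact to the asymptotic p-value in the
  presence of any cross-sample tie, which is conservative for tiny samples
  with ties.
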