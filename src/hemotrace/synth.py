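"""Synthetic PPCI cohort generator: AP/ECG signals plus a clinical table.

No raw catheter-lab recordings are publicly deposited, so every downstream
stage of the pipeline is exercised against this generator. It emulates the
statistical structure the analysis assumes:

- ~8.4% one-year mortality with planted covariate effects on the scale of the
  published cohort summary (age d ≈ 0.57, renal dysfunction φ ≈ 0.26, ...);
- arterial-pressure beats with a fast systolic upstroke (~30% of the cycle)
  and an exponential diastolic decay, per-beat SBP/DBP jitter, and a
  lead-II-like ECG with one QRS per beat;
- contiguous artifact blocks (motion spikes, flatlines, baseline wander) with
  a ground-truth noise mask, plus ground-truth R peaks and beat boundaries;
- non-survivors draw lower SBP/DBP and higher heart rate, the directions the
  clinical literature reports for post-STEMI mortality.

Everything is deterministic given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import published

#: systolic upstroke occupies this fraction of the cardiac cycle (AT < DT)
ASCENDING_FRACTION = 0.30
#: exponential decay rate of the diastolic run-off, in units of 1/DT
DIASTOLIC_DECAY = 3.0
#: between-subject morphology variation (SD of the two parameters above)
ASCENDING_FRACTION_SD = 0.025
DIASTOLIC_DECAY_SD = 0.4
#: onset of the first beat, seconds into the record
FIRST_BEAT_OFFSET = 0.25
#: per-beat jitter SDs
SBP_JITTER_MMHG = 1.5
DBP_JITTER_MMHG = 1.0
PERIOD_JITTER_FRAC = 0.02
#: additive measurement noise on the clean AP trace, mmHg
AP_NOISE_MMHG = 0.3

ARTIFACT_KINDS = ("spike", "flatline", "wander")
#: artifact blocks are contiguous, with lengths uniform in this range (s)
ARTIFACT_BLOCK_RANGE_S = (2.0, 10.0)

#: survivor-group hemodynamics; non-survivors are shifted (see GROUP_SHIFTS)
HEMODYNAMICS = {
    "sbp_mean": 125.0,
    "sbp_sd": 15.0,
    "dbp_mean": 80.0,
    "dbp_sd_resid": 6.69,  # residual SD given SBP
    "dbp_slope": 0.2933,   # regression of DBP on SBP
    "hr_mean": 76.0,
    "hr_sd": 11.0,
}
#: additive shifts for non-survivors (lower pressures, faster heart rate)
GROUP_SHIFTS = {"sbp": -10.0, "dbp_intercept": -3.0, "hr": +8.0}

#: planted covariate effects (died − survived), Cohen's d for continuous
#: covariates and φ for binary flags, on the scale of the published summary
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "age": 0.57,
    "male": -0.13,
    "height_cm": -0.30,
    "weight_kg": -0.35,
    "hypertension": 0.07,
    "diabetes": 0.05,
    "dyslipidemia": -0.06,
    "stroke_tia": 0.13,
    "pvd": 0.08,
    "renal_dysfunction": 0.26,
    "dialysis": 0.24,
    "ihd_history": -0.03,
    "pci_cabg": -0.04,
    "esp_s_per_min": -0.27,
    "est_s_per_beat": -0.46,
}

_CONTINUOUS_BASE = {
    # survivor-group mean and (shared) group SD
    "age": (63.56, 12.50),
    "height_cm": (171.93, 10.70),
    "weight_kg": (86.24, 20.00),
    "esp_s_per_min": (19.19, 3.25),
    "est_s_per_beat": (0.241, 0.042),
}
_BINARY_EXPOSURE = {
    name: published.exposure_rate(name)
    for name in published.BINARY_FACTORS
}


def max_feasible_phi(prevalence: float, exposure: float) -> float:
    """Largest |φ| a 2×2 table with these margins can carry."""
    pi, q = prevalence, exposure
    bound_died = np.sqrt(pi * (1 - q) / ((1 - pi) * q))   # P(present|died) <= 1
    bound_surv = np.sqrt(q * (1 - pi) / ((1 - q) * pi))   # P(present|surv) >= 0
    return float(min(bound_died, bound_surv))


def feasible_effect_sizes(
    prevalence: float, base: dict[str, float] | None = None, margin: float = 0.95
) -> dict[str, float]:
    """Default effect map with binary φ clipped to what the margins allow.

    Rare exposures (e.g. dialysis at 0.8%) cannot carry their published φ at
    prevalences far from the published 8.4%; the default map shrinks such
    effects toward the feasible boundary instead of failing.
    """
    base = dict(DEFAULT_EFFECT_SIZES if base is None else base)
    for name, eff in base.items():
        if name in _BINARY_EXPOSURE:
            cap = margin * max_feasible_phi(prevalence, _BINARY_EXPOSURE[name])
            base[name] = float(np.clip(eff, -cap, cap))
    return base


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one synthetic AP + ECG recording."""

    sampling_rate: float = 240.0
    duration: float = 60.0
    heart_rate: float = 75.0
    sbp: float = 120.0
    dbp: float = 80.0
    artifact_fraction: float = 0.0
    artifact_kinds: tuple[str, ...] = ARTIFACT_KINDS
    at_fraction: float = ASCENDING_FRACTION
    decay: float = DIASTOLIC_DECAY

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ValueError(f"sampling_rate must be >= 100 Hz, got {self.sampling_rate}")
        if not (20 < self.dbp < self.sbp < 300):
            raise ValueError(
                f"pressures must satisfy 20 < dbp < sbp < 300 mmHg, got "
                f"dbp={self.dbp}, sbp={self.sbp}"
            )
        if not (0 <= self.artifact_fraction < 0.9):
            raise ValueError(
                f"artifact_fraction must be in [0, 0.9), got {self.artifact_fraction}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        unknown = set(self.artifact_kinds) - set(ARTIFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
        if not (0.1 <= self.at_fraction < 0.5):
            raise ValueError(
                f"at_fraction must be in [0.1, 0.5) so AT < DT, got {self.at_fraction}"
            )
        if self.decay <= 0:
            raise ValueError("decay must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort."""

    n_subjects: int = 605
    prevalence: float = 0.0843
    seed: int = 0
    #: None -> published-scale defaults, clipped to feasibility (see
    #: :func:`feasible_effect_sizes`); an explicit map is validated strictly
    effect_sizes: dict[str, float] | None = None
    signal_spec: SignalSpec = field(default_factory=SignalSpec)

    def __post_init__(self) -> None:
        if self.effect_sizes is None:
            object.__setattr__(
                self, "effect_sizes", feasible_effect_sizes(self.prevalence)
            )
        if self.n_subjects < 20:
            raise ValueError(f"n_subjects must be >= 20, got {self.n_subjects}")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.prevalence * self.n_subjects < 2:
            raise ValueError("prevalence * n_subjects must be >= 2")
        for name, eff in self.effect_sizes.items():
            if not np.isfinite(eff):
                raise ValueError(f"effect size for {name!r} is not finite")
            if name in _BINARY_EXPOSURE or name == "male":
                if not (0 <= abs(eff) < 1):
                    raise ValueError(f"binary effect size |φ| for {name!r} must be < 1")


@dataclass
class SignalRecord:
    """One subject's synchronized AP + ECG traces with generator ground truth."""

    subject_id: str
    time: np.ndarray          # seconds, uniform grid
    ap: np.ndarray            # mmHg
    ecg: np.ndarray           # arbitrary units
    sampling_rate: float
    truth_r_peaks: np.ndarray       # sample indices, strictly increasing
    truth_noise_mask: np.ndarray    # boolean, True where corrupted
    truth_beat_bounds: np.ndarray   # (n_beats, 2) half-open index pairs

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.ap) == len(self.ecg) == n):
            raise ValueError("time/ap/ecg must have equal length")
        if np.any(np.diff(self.truth_r_peaks) <= 0):
            raise ValueError("truth_r_peaks must be strictly increasing")
        b = self.truth_beat_bounds
        if len(b) and (np.any(b[:, 1] <= b[:, 0]) or np.any(b[1:, 0] < b[:-1, 1])):
            raise ValueError("beat bounds must be ordered and non-overlapping")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def _beat_template(
    tau: np.ndarray,
    period: float,
    sbp: float,
    dbp: float,
    at_fraction: float = ASCENDING_FRACTION,
    decay: float = DIASTOLIC_DECAY,
) -> np.ndarray:
    """Asymmetric pulse on local time ``tau`` in [0, period)."""
    at = at_fraction * period
    dt = period - at
    p = np.empty_like(tau)
    rising = tau < at
    p[rising] = dbp + (sbp - dbp) * 0.5 * (1 - np.cos(np.pi * tau[rising] / at))
    x = (tau[~rising] - at) / dt
    k = decay
    p[~rising] = dbp + (sbp - dbp) * (np.exp(-k * x) - np.exp(-k)) / (1 - np.exp(-k))
    return p


def _add_bump(ecg: np.ndarray, fs: float, center_s: float, amp: float, width_s: float) -> None:
    n = len(ecg)
    half = 4 * width_s
    lo = max(0, int(np.floor((center_s - half) * fs)))
    hi = min(n, int(np.ceil((center_s + half) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    ecg[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def _inject_artifacts(
    ap: np.ndarray, fs: float, fraction: float, kinds: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Corrupt the trace in place; return the noise mask.

    Corruption comes as one sustained episode of back-to-back contiguous
    blocks (lengths uniform in 2–10 s, each block with its own artifact
    kind), emulating the prolonged disturbance of catheter manipulation
    rather than isolated bad samples.
    """
    n = len(ap)
    mask = np.zeros(n, dtype=bool)
    if fraction <= 0:
        return mask
    target = int(round(fraction * n))
    lo_s, hi_s = ARTIFACT_BLOCK_RANGE_S
    t_grid = np.arange(n) / fs
    # draw block lengths until the episode covers the target, trimming the last
    lengths: list[int] = []
    while sum(lengths) < target:
        lng = int(round(rng.uniform(lo_s, hi_s) * fs))
        lengths.append(min(lng, target - sum(lengths) + 1))
    total = min(sum(lengths), n)
    start0 = int(rng.integers(0, max(1, n - total + 1)))
    pos = start0
    for length in lengths:
        length = min(length, n - pos)
        if length <= 0:
            break
        start = pos
        block = slice(start, start + length)
        pos += length
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "spike":
            hits = rng.random(length) < 0.08
            ap[block] = np.where(
                hits,
                ap[block] + rng.uniform(60, 160, length) * rng.choice([-1.0, 1.0], length),
                ap[block] + rng.normal(0, 15, length),
            )
        elif kind == "flatline":
            ap[block] = float(ap.take(start))
        else:  # wander: slow drift plus broadband noise
            f = rng.uniform(0.05, 0.25)
            amp = rng.uniform(60, 120)
            phase = rng.uniform(0, 2 * np.pi)
            ap[block] += amp * np.sin(2 * np.pi * f * t_grid[block] + phase)
            ap[block] += rng.normal(0, 8, length)
        mask[block] = True
    return mask


def synth_signal(spec: SignalSpec, seed: int, subject_id: str = "S000") -> SignalRecord:
    """Generate one subject's record; identical seed ⇒ identical record."""
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    time = np.arange(n) / fs
    base_period = 60.0 / spec.heart_rate

    # beat onsets with period jitter
    onsets = [FIRST_BEAT_OFFSET]
    periods = []
    while True:
        period = base_period * (1 + PERIOD_JITTER_FRAC * rng.standard_normal())
        period = max(period, 0.25)
        if onsets[-1] >= spec.duration:
            break
        periods.append(period)
        onsets.append(onsets[-1] + period)
    onsets = np.asarray(onsets[:-1])
    periods = np.asarray(periods[: len(onsets)])
    keep = onsets < spec.duration
    onsets, periods = onsets[keep], periods[keep]

    ap = np.full(n, spec.dbp, dtype=float)
    ecg = np.zeros(n, dtype=float)
    r_peaks = []
    bounds = []
    for onset, period in zip(onsets, periods):
        sbp_i = spec.sbp + SBP_JITTER_MMHG * rng.standard_normal()
        dbp_i = spec.dbp + DBP_JITTER_MMHG * rng.standard_normal()
        lo = int(round(onset * fs))
        hi = min(n, int(round((onset + period) * fs)))
        if hi <= lo:
            continue
        tau = time[lo:hi] - onset
        ap[lo:hi] = _beat_template(tau, period, sbp_i, dbp_i, spec.at_fraction, spec.decay)
        r_peaks.append(lo)
        if hi < n or abs((onset + period) - spec.duration) * fs < 1:
            bounds.append((lo, hi))
        # ECG complexes around the R peak
        _add_bump(ecg, fs, onset - 0.22 * period, 0.12, 0.025)   # P
        _add_bump(ecg, fs, onset - 0.025, -0.15, 0.008)          # Q
        _add_bump(ecg, fs, onset, 1.0, 0.012)                    # R
        _add_bump(ecg, fs, onset + 0.025, -0.20, 0.008)          # S
        _add_bump(ecg, fs, onset + 0.35 * period, 0.25, 0.050)   # T

    ap += AP_NOISE_MMHG * rng.standard_normal(n)
    ecg += 0.01 * rng.standard_normal(n)
    mask = _inject_artifacts(ap, fs, spec.artifact_fraction, spec.artifact_kinds, rng)

    return SignalRecord(
        subject_id=subject_id,
        time=time,
        ap=ap,
        ecg=ecg,
        sampling_rate=fs,
        truth_r_peaks=np.asarray(r_peaks, dtype=int),
        truth_noise_mask=mask,
        truth_beat_bounds=np.asarray(bounds, dtype=int).reshape(-1, 2),
    )


def plant_binary_rates(prevalence: float, exposure: float, phi: float) -> tuple[float, float]:
    """Solve the 2×2 cell probabilities for a planted φ.

    Returns (P(present | survived), P(present | died)). Raises if the target
    association is infeasible for the given margins.
    """
    pi, q = prevalence, exposure
    p11 = q * pi + phi * np.sqrt(q * (1 - q) * pi * (1 - pi))
    p_died = p11 / pi
    p_surv = (q - p11) / (1 - pi)
    if not (0 <= p_died <= 1 and 0 <= p_surv <= 1):
        raise ValueError(
            f"phi={phi} infeasible for prevalence={pi}, exposure={q}: "
            f"cell probabilities ({p_surv:.3f}, {p_died:.3f}) leave [0, 1]"
        )
    return float(p_surv), float(p_died)


@dataclass
class Cohort:
    """Synthetic cohort: clinical table, optional signals, generator truth."""

    spec: CohortSpec
    clinical: pd.DataFrame
    signal_truth: pd.DataFrame
    records: list[SignalRecord] | None = None


def synth_cohort(cspec: CohortSpec, generate_signals: bool = True) -> Cohort:
    """Generate the full cohort.

    The number of deaths is fixed at round(prevalence · n_subjects) so the
    class balance matches the targeted prevalence exactly; which subjects die
    is randomized. Signal generation can be skipped for tabular-only studies.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_subjects
    n_died = int(round(cspec.prevalence * n))
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_died]] = 1

    eff = cspec.effect_sizes
    clinical: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:04d}" for i in range(n)]),
    }
    for name, (mean_surv, sd) in _CONTINUOUS_BASE.items():
        d = eff.get(name, 0.0)
        clinical[name] = rng.normal(mean_surv + d * sd * y, sd)
    for name in published.BINARY_FACTORS:
        phi = eff.get(name, 0.0)
        p_surv, p_died = plant_binary_rates(cspec.prevalence, _BINARY_EXPOSURE[name], phi)
        p = np.where(y == 1, p_died, p_surv)
        clinical[name] = (rng.random(n) < p).astype(int)
    clinical["outcome"] = y
    clinical_df = pd.DataFrame(clinical)

    # per-subject hemodynamics (non-survivors: lower pressures, faster HR)
    h = HEMODYNAMICS
    sbp_mean = h["sbp_mean"] + GROUP_SHIFTS["sbp"] * y
    sbp = rng.normal(sbp_mean, h["sbp_sd"])
    dbp = (
        h["dbp_mean"]
        + GROUP_SHIFTS["dbp_intercept"] * y
        + h["dbp_slope"] * (sbp - sbp_mean)
        + rng.normal(0, h["dbp_sd_resid"], n)
    )
    sbp = np.clip(sbp, 85, 210)
    dbp = np.clip(dbp, 45, sbp - 20)
    hr = np.clip(rng.normal(h["hr_mean"] + GROUP_SHIFTS["hr"] * y, h["hr_sd"]), 45, 135)
    duration = cspec.signal_spec.duration * rng.uniform(0.85, 1.15, n)
    at_frac = np.clip(
        rng.normal(cspec.signal_spec.at_fraction, ASCENDING_FRACTION_SD, n), 0.22, 0.40
    )
    decay = np.clip(rng.normal(cspec.signal_spec.decay, DIASTOLIC_DECAY_SD, n), 1.8, 4.5)
    truth_df = pd.DataFrame(
        {
            "subject_id": clinical_df["subject_id"],
            "true_sbp": sbp,
            "true_dbp": dbp,
            "true_heart_rate": hr,
            "duration": duration,
            "at_fraction": at_frac,
            "decay": decay,
            "outcome": y,
        }
    )

    records = None
    if generate_signals:
        child_seeds = np.random.SeedSequence(cspec.seed).generate_state(n + 1)[1:]
        records = []
        for i in range(n):
            spec_i = SignalSpec(
                sampling_rate=cspec.signal_spec.sampling_rate,
                duration=float(duration[i]),
                heart_rate=float(hr[i]),
                sbp=float(sbp[i]),
                dbp=float(dbp[i]),
                artifact_fraction=cspec.signal_spec.artifact_fraction,
                artifact_kinds=cspec.signal_spec.artifact_kinds,
                at_fraction=float(at_frac[i]),
                decay=float(decay[i]),
            )
            records.append(
                synth_signal(spec_i, seed=int(child_seeds[i] % (2**31)), subject_id=f"S{i:04d}")
            )
    return Cohort(spec=cspec, clinical=clinical_df, signal_truth=truth_df, records=records)
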