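"""Per-beat AP waveform features, subject-level aggregation, and pruning.

Each clean AP segment is split into individual pulses (trough to trough, one
per cardiac cycle). From each pulse p(t) the per-beat features are computed:

=====  =======================================================
HB     60 / beat duration (bpm)
DBP    min(p) (mmHg)                 SBP   max(p) (mmHg)
PP     SBP − DBP                     MAP   (2·DBP + SBP) / 3
AT     time to systolic peak (s)     DT    duration − AT (s)
AOC    ∫ p dt (mmHg·s)               UA    ∫ p dt over t ≤ AT
DA     AOC − UA                      AR    DA / UA
MS     max(p′) (mmHg/s)              FD    Katz fractal dimension
SK     E[(p−μ)³]/σ³                  KU    E[(p−μ)⁴]/σ⁴ (not excess)
SE     Shannon entropy of the unit-sum PSD (bits)
Pave   Σ PSD / n (power)
=====  =======================================================

plus the subject-level OT, the whole recording span in seconds. Multi-beat
features are aggregated per subject with a 20% trimmed mean (20% of the beats
dropped from each tail); OT passes through untrimmed. Finally, features with
pairwise |Pearson r| above 0.7 are pruned greedily, keeping the feature that
appears earlier in the canonical order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sg

from .denoise import katz_fd

#: canonical feature order; used for pruning and tie-breaks
FEATURE_ORDER = [
    "HB", "DBP", "SBP", "PP", "MAP", "OT", "AT", "DT", "AOC",
    "UA", "DA", "AR", "MS", "FD", "SK", "KU", "SE", "Pave",
]
#: per-beat features (all but the subject-level OT)
BEAT_FEATURES = [f for f in FEATURE_ORDER if f != "OT"]

MIN_BEAT_S = 0.25
MAX_BEAT_S = 2.0
TRIM_FRACTION = 0.20
CORRELATION_THRESHOLD = 0.7


@dataclass
class BeatWaveform:
    """One cleaned AP pulse, trough to trough."""

    p: np.ndarray  # mmHg
    t: np.ndarray  # seconds from beat onset
    sampling_rate: float
    start_index: int = 0  # offset of the beat onset within its source segment

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def is_valid(self) -> bool:
        """Duration in [0.25, 2] s, non-constant, exactly one systolic peak."""
        if not (MIN_BEAT_S <= self.duration <= MAX_BEAT_S):
            return False
        if np.ptp(self.p) == 0:
            return False
        prom = 0.25 * np.ptp(self.p)
        peaks, _ = sg.find_peaks(self.p, prominence=prom)
        return len(peaks) == 1


def segment_beats(
    segment: np.ndarray,
    r_peaks: np.ndarray,
    sampling_rate: float,
) -> tuple[list[BeatWaveform], int]:
    """Split a clean AP segment into beats delimited by diastolic troughs.

    ``r_peaks`` are sample indices *within the segment*. Near each R peak
    the diastolic foot is located as the AP minimum within an asymmetric
    window (5% of the RR interval before R to 30% after — the pressure foot
    follows the R wave); consecutive feet delimit one beat. Beats failing
    the waveform invariants are rejected and counted.

    Returns (beats, n_rejected).
    """
    segment = np.asarray(segment, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    r_peaks = r_peaks[(r_peaks >= 0) & (r_peaks < len(segment))]
    if len(r_peaks) < 2:
        return [], 0
    rr = np.median(np.diff(r_peaks))
    before = max(1, int(round(0.05 * rr)))
    after = max(2, int(round(0.30 * rr)))
    troughs = []
    for r in r_peaks:
        lo, hi = max(0, r - before), min(len(segment), r + after + 1)
        troughs.append(lo + int(np.argmin(segment[lo:hi])))
    troughs = sorted(set(troughs))
    beats, rejected = [], 0
    for lo, hi in zip(troughs[:-1], troughs[1:]):
        p = segment[lo : hi + 1]
        t = np.arange(len(p)) / sampling_rate
        beat = BeatWaveform(p=p, t=t, sampling_rate=sampling_rate, start_index=lo)
        if beat.is_valid():
            beats.append(beat)
        else:
            rejected += 1
    return beats, rejected


def beat_feature_vector(b: BeatWaveform) -> dict[str, float]:
    """All per-beat features of one pulse (see module docstring)."""
    p, t = b.p, b.t
    duration = b.duration
    dbp, sbp = float(np.min(p)), float(np.max(p))
    i_peak = int(np.argmax(p))
    at = float(t[i_peak])
    aoc = float(np.trapezoid(p, t))
    ua = float(np.trapezoid(p[: i_peak + 1], t[: i_peak + 1]))
    da = float(np.trapezoid(p[i_peak:], t[i_peak:]))
    dt = float(t[-1] - t[i_peak])
    dp = np.gradient(p, t)
    mu, sigma = float(np.mean(p)), float(np.std(p))
    if sigma == 0:
        raise ValueError("constant beat: moments undefined")
    sk = float(np.mean((p - mu) ** 3) / sigma**3)
    ku = float(np.mean((p - mu) ** 4) / sigma**4)
    _, psd = sg.periodogram(p - mu, fs=b.sampling_rate)
    total = float(np.sum(psd))
    if total > 0:
        q = psd / total
        q = q[q > 0]
        se = float(-np.sum(q * np.log2(q)))
    else:
        se = 0.0
    return {
        "HB": 60.0 / duration,
        "DBP": dbp,
        "SBP": sbp,
        "PP": sbp - dbp,
        "MAP": (2 * dbp + sbp) / 3.0,
        "AT": at,
        "DT": dt,
        "AOC": aoc,
        "UA": ua,
        "DA": da,
        "AR": da / ua if ua != 0 else np.nan,
        "MS": float(np.max(dp)),
        "FD": katz_fd(p),
        "SK": sk,
        "KU": ku,
        "SE": se,
        "Pave": total / len(p),
    }


def overall_time(time: np.ndarray) -> float:
    """Whole recording span: last timestamp minus first, seconds."""
    time = np.asarray(time, dtype=float)
    if len(time) == 0:
        raise ValueError("empty record has no overall time")
    return float(time[-1] - time[0])


def trimmed_mean(values: np.ndarray, trim: float = TRIM_FRACTION) -> float:
    """Mean after dropping floor(trim·n) values from each tail."""
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) == 0:
        raise ValueError("trimmed mean of an empty sequence")
    if not 0 <= trim < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    k = int(np.floor(trim * len(values)))
    return float(np.mean(values[k : len(values) - k]))


def aggregate_beats(
    beats: list[BeatWaveform],
    ot: float,
    trim: float = TRIM_FRACTION,
) -> dict[str, float]:
    """Subject-level feature row: trimmed mean over beats, OT untrimmed."""
    if not beats:
        raise ValueError("no beats to aggregate")
    per_beat = pd.DataFrame([beat_feature_vector(b) for b in beats])
    row = {name: trimmed_mean(per_beat[name].to_numpy(), trim) for name in BEAT_FEATURES}
    row["OT"] = float(ot)
    row["n_beats_used"] = len(beats)
    return row


def prune_correlated(
    X: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    order: list[str] | None = None,
) -> list[str]:
    """Greedy correlation pruning.

    Features are visited in the canonical order; a feature is retained only
    if its absolute Pearson correlation with every already-retained feature
    is at or below the threshold. Constant columns are dropped with a
    warning (their correlation is undefined).
    """
    if len(X) < 3:
        raise ValueError("need >= 3 subjects for correlation pruning")
    order = order or [f for f in FEATURE_ORDER if f in X.columns]
    order = order + [c for c in X.columns if c not in order]
    corr = X[order].corr().abs()
    retained: list[str] = []
    for name in order:
        if X[name].nunique() < 2:
            warnings.warn(f"feature {name!r} is constant; dropped from pruning")
            continue
        if all(corr.loc[name, kept] <= threshold for kept in retained):
            retained.append(name)
    return retained
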