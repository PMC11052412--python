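"""Adaptive-window denoising of the arterial-pressure trace.

The AP signal is tiled with windows of six heart cycles at 50% overlap. For
each window ten characteristics are computed — three segment means, four
standard deviations (whole window + three segments), and three segment Katz
fractal dimensions — and screened against physiological thresholds; windows
failing any screen are discarded. The union of kept windows, merged into
maximal disjoint ranges on the original (unfiltered) AP signal, is the clean
portion used for feature extraction.

Mean/SD screening runs on the raw AP window (the thresholds are absolute
pressures); fractal-dimension screening runs on the 0.4 Hz high-pass output,
where baseline wander is removed and residual broadband noise stands out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sg

from .qrs import RPeakSet, detect_r_peaks, heart_cycle_length
from .synth import SignalRecord

#: high-pass cutoff for the screened signal, Hz
HIGHPASS_CUTOFF_HZ = 0.4
#: window length in heart cycles, and overlap fraction
WINDOW_CYCLES = 6
WINDOW_OVERLAP = 0.5


@dataclass(frozen=True)
class DenoiseThresholds:
    """Keep-ranges for the window characteristics.

    Defaults: segment means within 20–250 mmHg (pressures outside are
    non-physiological), SDs within 1–60 mmHg (a near-zero SD is a flatline,
    a huge SD is impulsive noise), Katz FD within 1.0–1.10 (clean pressure
    pulses sit barely above 1; corrupted windows are markedly higher).
    """

    mean_range: tuple[float, float] = (20.0, 250.0)
    sd_range: tuple[float, float] = (1.0, 60.0)
    fd_range: tuple[float, float] = (1.0, 1.10)

    def __post_init__(self) -> None:
        for name in ("mean_range", "sd_range", "fd_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper bound")


@dataclass
class APWindow:
    """One analysis window: raw samples plus the high-pass-filtered samples."""

    start: int
    end: int  # half-open
    samples: np.ndarray
    hp_samples: np.ndarray


@dataclass
class WindowStats:
    """Ten screening characteristics of one window."""

    seg_means: tuple[float, float, float]
    sds: tuple[float, float, float, float]  # whole-window SD first
    seg_fds: tuple[float, float, float]


@dataclass
class CleanSegments:
    """Kept index ranges (half-open, disjoint, sorted) of one record."""

    ranges: list[tuple[int, int]]
    n_windows: int
    n_kept: int
    poor_quality: bool

    def kept_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for lo, hi in self.ranges:
            mask[lo:hi] = True
        return mask


def highpass_ap(ap: np.ndarray, sampling_rate: float, cutoff: float = HIGHPASS_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass; removes DC and drift."""
    if cutoff >= sampling_rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({sampling_rate / 2} Hz)")
    sos = sg.butter(4, cutoff, btype="highpass", fs=sampling_rate, output="sos")
    return sg.sosfiltfilt(sos, np.asarray(ap, dtype=float))


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of a series on a unit-index abscissa.

    D = log10(n) / (log10(n) + log10(d / L)) with L the total polyline
    length, d the maximal distance from the first vertex, and n the number
    of steps. A straight ramp gives exactly 1; rougher series give more.
    Constant series are rejected (a flatline must not masquerade as a clean
    simple signal).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples for the Katz fractal dimension")
    if np.ptp(x) == 0:
        raise ValueError("Katz fractal dimension undefined for a constant series")
    dy = np.diff(x)
    length = float(np.sum(np.sqrt(1.0 + dy**2)))
    idx = np.arange(len(x), dtype=float)
    dist = float(np.max(np.hypot(idx - idx[0], x - x[0])))
    n_steps = len(x) - 1
    return float(np.log10(n_steps) / (np.log10(n_steps) + np.log10(dist / length)))


def window_signal(
    ap: np.ndarray,
    cycle_length: float,
    sampling_rate: float,
    hp: np.ndarray | None = None,
) -> list[APWindow]:
    """Tile the signal with 6-cycle windows at 50% overlap.

    The trailing remainder shorter than one window is dropped. Returns an
    empty list (with a warning) if the signal is shorter than one window.
    """
    ap = np.asarray(ap, dtype=float)
    if hp is None:
        hp = highpass_ap(ap, sampling_rate)
    win_len = int(round(WINDOW_CYCLES * cycle_length * sampling_rate))
    step = max(1, int(round(win_len * (1 - WINDOW_OVERLAP))))
    if len(ap) < win_len:
        warnings.warn("signal shorter than one analysis window; no windows produced")
        return []
    starts = range(0, len(ap) - win_len + 1, step)
    return [APWindow(start=s, end=s + win_len, samples=ap[s : s + win_len], hp_samples=hp[s : s + win_len]) for s in starts]


def _segments(x: np.ndarray) -> list[np.ndarray]:
    """Three near-equal parts; the remainder goes to the last segment."""
    third = len(x) // 3
    return [x[:third], x[third : 2 * third], x[2 * third :]]


def window_stats(w: APWindow) -> WindowStats:
    """Ten characteristics: segment means and SDs on the raw window, segment
    Katz FDs on the high-pass window."""
    raw_segs = _segments(w.samples)
    hp_segs = _segments(w.hp_samples)
    seg_means = tuple(float(np.mean(s)) for s in raw_segs)
    sds = (float(np.std(w.samples)),) + tuple(float(np.std(s)) for s in raw_segs)
    fds = []
    for s in hp_segs:
        try:
            fds.append(katz_fd(s))
        except ValueError:  # constant segment: force a discard downstream
            fds.append(np.inf)
    return WindowStats(seg_means=seg_means, sds=sds, seg_fds=tuple(fds))


def classify_window(stats: WindowStats, thr: DenoiseThresholds) -> bool:
    """True = keep. A window is kept iff every characteristic is in range."""
    in_range = lambda v, rng: rng[0] <= v <= rng[1]
    return (
        all(in_range(m, thr.mean_range) for m in stats.seg_means)
        and all(in_range(s, thr.sd_range) for s in stats.sds)
        and all(in_range(f, thr.fd_range) for f in stats.seg_fds)
    )


def clean_segments(
    record: SignalRecord,
    thr: DenoiseThresholds | None = None,
    peaks: RPeakSet | None = None,
) -> CleanSegments:
    """Screen all windows of a record and merge the kept ones.

    Ranges are reported on the original (unfiltered) AP signal as maximal
    disjoint half-open index intervals. A record with zero kept windows is
    flagged poor-quality (such subjects are excluded from the analysis).
    """
    thr = thr or DenoiseThresholds()
    if peaks is None:
        peaks = detect_r_peaks(record.ecg, record.sampling_rate)
    if len(peaks) < 2:
        return CleanSegments(ranges=[], n_windows=0, n_kept=0, poor_quality=True)
    cycle = heart_cycle_length(peaks)
    hp = highpass_ap(record.ap, record.sampling_rate)
    windows = window_signal(record.ap, cycle, record.sampling_rate, hp=hp)
    kept = [w for w in windows if classify_window(window_stats(w), thr)]
    ranges: list[tuple[int, int]] = []
    for w in kept:
        if ranges and w.start <= ranges[-1][1]:
            ranges[-1] = (ranges[-1][0], max(ranges[-1][1], w.end))
        else:
            ranges.append((w.start, w.end))
    return CleanSegments(
        ranges=ranges,
        n_windows=len(windows),
        n_kept=len(kept),
        poor_quality=len(kept) == 0,
    )
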