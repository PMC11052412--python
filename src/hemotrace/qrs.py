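"""Pan–Tompkins R-peak detection and heart-cycle length.

The classic pipeline: band-pass filtering (5–15 Hz) to suppress baseline
drift and P/T waves, differentiation, squaring, moving-window integration
(150 ms), then adaptive thresholding with running signal/noise peak estimates
and a 200 ms refractory period. Detected integration peaks are mapped back to
the R-wave maximum of the band-passed ECG.

The adaptive thresholds are derived from the signal's own peak amplitudes, so
detection is invariant under positive amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sg

#: band-pass corner frequencies, Hz
BAND_HZ = (5.0, 15.0)
#: moving-window integration length, seconds
INTEGRATION_WINDOW_S = 0.150
#: minimum spacing between accepted R peaks, seconds
REFRACTORY_S = 0.200
#: half-width of the window used to refine peak location on the band-passed ECG
REFINE_WINDOW_S = 0.075
#: minimum signal length, seconds
MIN_SIGNAL_S = 2.0


@dataclass(frozen=True)
class RPeakSet:
    """Detected R-peak sample positions, strictly increasing."""

    indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.sampling_rate


def detect_r_peaks(ecg: np.ndarray, sampling_rate: float) -> RPeakSet:
    """Detect R peaks in a lead-II-like ECG trace.

    Raises if the signal is shorter than the filter warm-up (2 s) or the
    sampling rate is below 100 Hz; a zero-variance signal yields an empty set.
    """
    ecg = np.asarray(ecg, dtype=float)
    fs = float(sampling_rate)
    if fs < 100:
        raise ValueError(f"sampling_rate must be >= 100 Hz, got {fs}")
    if len(ecg) < MIN_SIGNAL_S * fs:
        raise ValueError(
            f"signal too short for filter warm-up: need >= {MIN_SIGNAL_S} s"
        )
    if np.ptp(ecg) == 0:
        return RPeakSet(indices=np.empty(0, dtype=int), sampling_rate=fs)

    sos = sg.butter(2, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    band = sg.sosfiltfilt(sos, ecg)
    deriv = np.gradient(band) * fs
    squared = deriv**2
    win = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sg.find_peaks(integrated, distance=refractory)
    if len(cand) == 0:
        return RPeakSet(indices=np.empty(0, dtype=int), sampling_rate=fs)

    # adaptive thresholding with running signal/noise peak estimates
    warm = integrated[: int(2 * fs)]
    spki = float(np.max(warm)) / 3.0
    npki = float(np.mean(warm)) / 2.0
    accepted = []
    for i in cand:
        level = integrated[i]
        threshold = npki + 0.25 * (spki - npki)
        if level > threshold:
            accepted.append(i)
            spki = 0.125 * level + 0.875 * spki
        else:
            npki = 0.125 * level + 0.875 * npki

    # refine: locate the band-passed ECG maximum near each integration peak
    half = int(round(REFINE_WINDOW_S * fs))
    refined = []
    for i in accepted:
        lo, hi = max(0, i - half), min(len(band), i + half + 1)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    if len(refined) > 1:  # enforce refractory after refinement
        keep = [0]
        for j in range(1, len(refined)):
            if refined[j] - refined[keep[-1]] > refractory:
                keep.append(j)
        refined = refined[keep]
    return RPeakSet(indices=refined, sampling_rate=fs)


def heart_cycle_length(peaks: RPeakSet) -> float:
    """Median inter-peak interval in seconds (robust to missed/extra beats)."""
    if len(peaks) < 2:
        raise ValueError("need >= 2 R peaks to estimate the heart cycle length")
    intervals = np.diff(peaks.times)
    return float(np.median(intervals))


def heart_rate_bpm(peaks: RPeakSet) -> float:
    """Heart rate 60 / cycle-length, beats per minute."""
    return 60.0 / heart_cycle_length(peaks)
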