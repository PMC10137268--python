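"""ECG cleaning and R-peak detection.

Turns a raw single-lead ECG trace into an RR-interval series: a zero-phase
band-pass (plus optional mains notch) removes baseline drift and
high-frequency noise, a differential-threshold detector locates R peaks,
and successive peak positions are differenced into cardiac-cycle durations
in milliseconds.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord",
    "RRSeries",
    "denoise",
    "detect_r_peaks",
    "peaks_to_rr",
    "ecg_to_rr",
]


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples : array-like
        Voltage samples, arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Start time of the record in seconds (optional bookkeeping).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def replace(self, **kwargs) -> "ECGRecord":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class RRSeries:
    """Ordered cardiac-cycle (RR interval) durations in milliseconds."""

    rr: np.ndarray
    peak_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "rr", rr)
        if rr.size and (not np.all(np.isfinite(rr)) or np.any(rr <= 0)):
            raise ValueError("RR intervals must be finite and positive")
        if self.peak_indices is not None:
            idx = np.asarray(self.peak_indices, dtype=np.int64)
            object.__setattr__(self, "peak_indices", idx)

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def onsets_ms(self) -> np.ndarray:
        """Start time of each interval, taking the first R peak as t=0."""
        return np.concatenate([[0.0], np.cumsum(self.rr)[:-1]])

    @property
    def total_ms(self) -> float:
        return float(np.sum(self.rr))


def denoise(
    ecg: ECGRecord,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    notch_hz: float | None = None,
    notch_q: float = 30.0,
    order: int = 2,
) -> ECGRecord:
    """Zero-phase band-pass (and optional mains notch) cleaning.

    The high-pass corner removes DC offset and baseline drift, the low-pass
    corner suppresses broadband high-frequency noise, and the optional IIR
    notch attenuates power-line interference.  Filtering is forward-backward
    (``sosfiltfilt``), so no phase distortion shifts the R peaks.
    """
    x = np.asarray(ecg.samples, dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("ECG contains non-finite samples")
    nyq = ecg.fs / 2.0
    if not (0.0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={ecg.fs} Hz"
        )
    if x.size == 0:
        return ecg.replace(samples=x)

    # notch first: removing mains interference before the band-pass keeps the
    # slow-settling high-pass stage from smearing it into edge transients
    y = x
    if notch_hz is not None:
        if not 0 < notch_hz < nyq:
            raise ValueError(f"notch frequency {notch_hz} outside (0, fs/2)")
        b, a = signal.iirnotch(notch_hz, notch_q, fs=ecg.fs)
        padlen = min(len(y) - 1, int(3 * notch_q / notch_hz * ecg.fs))
        y = signal.filtfilt(b, a, y, padlen=padlen)

    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=ecg.fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=ecg.fs, output="sos")
    y = signal.sosfiltfilt(sos, y)
    return ecg.replace(samples=y)


def _snap_to_local_max(x: np.ndarray, i: int) -> int:
    """Walk uphill from ``i`` to the nearest local maximum of ``x``."""
    n = len(x)
    while i + 1 < n and x[i + 1] > x[i]:
        i += 1
    while i - 1 >= 0 and x[i - 1] > x[i]:
        i -= 1
    return i


def detect_r_peaks(
    ecg: ECGRecord,
    threshold_frac: float = 0.3,
    refractory_s: float = 0.2,
    window_s: float = 2.0,
) -> np.ndarray:
    """Differential-threshold R-peak detector.

    The first difference of the signal is compared against an adaptive
    threshold equal to ``threshold_frac`` times the rolling maximum of the
    absolute difference over a ``window_s`` window (the window should span at
    least one cardiac cycle so every neighbourhood contains a QRS slope).
    Contiguous supra-threshold runs are collapsed to the local signal maximum
    they straddle, and a refractory period keeps only the taller of two peaks
    closer than ``refractory_s``.

    Returns strictly increasing 0-based sample indices; a flat trace yields
    an empty array.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    x = np.asarray(ecg.samples, dtype=float)
    if x.size < 3:
        return np.empty(0, dtype=np.int64)

    d = np.abs(np.diff(x))
    win = max(3, int(round(window_s * ecg.fs)) | 1)
    local_max = maximum_filter1d(d, size=win, mode="nearest")
    thr = threshold_frac * local_max
    mask = (d > thr) & (thr > 0)
    if not mask.any():
        return np.empty(0, dtype=np.int64)

    # group contiguous supra-threshold runs of the difference signal; run
    # [i0, i1] in diff coordinates straddles samples i0 .. i1+1
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])

    peaks: list[int] = []
    refractory = int(round(refractory_s * ecg.fs))
    for s, e in zip(starts, ends):
        lo, hi = idx[s], idx[e] + 2  # inclusive sample span of the run
        p = lo + int(np.argmax(x[lo:hi]))
        p = _snap_to_local_max(x, p)
        if peaks and p - peaks[-1] < refractory:
            if x[p] > x[peaks[-1]]:
                peaks[-1] = p
        elif not peaks or p > peaks[-1]:
            peaks.append(p)
    return np.asarray(peaks, dtype=np.int64)


def peaks_to_rr(peaks: np.ndarray, fs: float) -> RRSeries:
    """Difference R-peak sample indices into RR intervals in milliseconds."""
    peaks = np.asarray(peaks, dtype=np.int64)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if peaks.size < 2:
        return RRSeries(rr=np.empty(0), peak_indices=peaks)
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak indices must be strictly increasing")
    rr = np.diff(peaks) / fs * 1000.0
    return RRSeries(rr=rr, peak_indices=peaks)


def ecg_to_rr(
    ecg: ECGRecord,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    notch_hz: float | None = None,
    threshold_frac: float = 0.3,
    refractory_s: float = 0.2,
) -> RRSeries:
    """Convenience chain: denoise -> detect R peaks -> RR series."""
    clean = denoise(ecg, low_hz=low_hz, high_hz=high_hz, notch_hz=notch_hz)
    peaks = detect_r_peaks(clean, threshold_frac=threshold_frac, refractory_s=refractory_s)
    logger.info("detected %d R peaks over %.1f s", len(peaks), ecg.duration_s)
    return peaks_to_rr(peaks, ecg.fs)
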