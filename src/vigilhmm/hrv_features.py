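"""Time- and frequency-domain HRV features over fixed-length windows.

Implements the standard short-term heart-rate-variability indices: mean and
instantaneous heart rate, SDNN (standard deviation of RR intervals), RMSSD
(root mean square of successive RR differences), and the integrated spectral
power of the RR tachogram in the low-frequency (0.04-0.15 Hz) and
high-frequency (0.15-0.40 Hz) bands, plus their ratio.  Features are
computed per non-overlapping window (default 60 s) of cumulative RR time.

A ``literal`` switch on the time-domain indices evaluates an alternative
formulation in which the dispersion statistics are taken over the series of
*successive RR differences* rather than the intervals themselves; the
default follows the universal SDNN/RMSSD definitions.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .ecg_preprocess import RRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "instantaneous_hr",
    "sdnn",
    "rmssd",
    "band_power",
    "window_features",
    "FEATURE_COLUMNS",
]

#: low- and high-frequency bands (Hz), half-open (lo, hi]
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

FEATURE_COLUMNS = [
    "window_start",
    "n_beats",
    "hr_mean",
    "sdnn",
    "rmssd",
    "lfp",
    "hfp",
    "lf_hf",
]


def _as_rr_array(rr) -> np.ndarray:
    if isinstance(rr, RRSeries):
        rr = rr.rr
    rr = np.asarray(rr, dtype=float)
    if rr.size and (not np.all(np.isfinite(rr)) or np.any(rr <= 0)):
        raise ValueError("RR intervals must be finite and positive")
    return rr


def instantaneous_hr(rr) -> np.ndarray:
    """Instantaneous heart rate HR(n) = 60 / t(n), in beats per minute."""
    rr = _as_rr_array(rr)
    if rr.size == 0:
        raise ValueError("empty RR series")
    return 60000.0 / rr


def sdnn(rr, literal: bool = False) -> float:
    """Standard deviation of the RR intervals (ms), sample divisor N-1.

    With ``literal=True`` the statistic is instead the dispersion of the
    first differences delta(n) = t(n) - t(n-1) about their mean, with the
    same N-1 divisor (N intervals give N-1 differences).
    """
    rr = _as_rr_array(rr)
    if rr.size < 2:
        raise ValueError("SDNN requires at least 2 intervals")
    if literal:
        d = np.diff(rr)
        return float(np.sqrt(np.sum((d - d.mean()) ** 2) / (rr.size - 1)))
    return float(np.std(rr, ddof=1))


def rmssd(rr, literal: bool = False) -> float:
    """Root mean square of successive RR differences (ms).

    ``literal=True`` evaluates the RMS of *second* differences with divisor
    N-2 instead.
    """
    rr = _as_rr_array(rr)
    if rr.size < 2:
        raise ValueError("RMSSD requires at least 2 intervals")
    d = np.diff(rr)
    if literal:
        if rr.size < 3:
            raise ValueError("literal RMSSD requires at least 3 intervals")
        dd = np.diff(d)
        return float(np.sqrt(np.sum(dd**2) / (rr.size - 2)))
    return float(np.sqrt(np.mean(d**2)))


def band_power(
    rr,
    f_lo: float,
    f_hi: float,
    resample_hz: float = 4.0,
    nperseg: int = 256,
) -> float:
    """Integrated power of the RR tachogram over the band (f_lo, f_hi].

    The irregularly sampled tachogram (interval duration versus beat time) is
    resampled onto a uniform grid by cubic interpolation, mean-centred, and
    its spectrum estimated with a windowed averaged periodogram (Welch);
    band power is the trapezoidal integral of the density over the band.
    Units are ms^2.
    """
    rr = _as_rr_array(rr)
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if rr.size < 4:
        raise ValueError("band power requires at least 4 beats")
    t = np.cumsum(rr) / 1000.0  # beat times, s
    duration = t[-1] - t[0]
    if f_lo > 0 and 1.0 / duration >= f_lo:
        warnings.warn(
            f"window of {duration:.1f} s cannot resolve {f_lo} Hz",
            stacklevel=2,
        )
    kind = "cubic" if rr.size >= 4 else "linear"
    f_interp = interpolate.interp1d(t, rr, kind=kind)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    x = f_interp(grid)
    x = x - x.mean()
    freqs, psd = signal.welch(x, fs=resample_hz, nperseg=min(nperseg, len(x)))
    mask = (freqs > f_lo) & (freqs <= f_hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def window_features(
    rr,
    window_s: float = 60.0,
    drop_partial: bool = True,
    min_beats: int = 4,
    literal: bool = False,
    resample_hz: float = 4.0,
) -> pd.DataFrame:
    """Per-window HRV feature table over non-overlapping windows.

    Windows are laid out on cumulative RR time starting at the first beat; an
    interval belongs to the window containing its onset.  Windows with fewer
    than ``min_beats`` intervals are dropped with a warning, as is a trailing
    partial window unless ``drop_partial=False``.

    Returns a DataFrame with columns ``window_start`` (s), ``n_beats``,
    ``hr_mean`` (bpm), ``sdnn``, ``rmssd`` (ms), ``lfp``, ``hfp`` (ms^2) and
    ``lf_hf``.
    """
    if window_s <= 0:
        raise ValueError("window length must be positive")
    rr = _as_rr_array(rr)
    if rr.size == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)

    w_ms = window_s * 1000.0
    onsets = np.concatenate([[0.0], np.cumsum(rr)[:-1]])
    total = float(np.sum(rr))
    n_windows = int(total // w_ms)
    if not drop_partial and total % w_ms > 0:
        n_windows += 1

    rows = []
    win_index = np.floor(onsets / w_ms).astype(int)
    for k in range(n_windows):
        chunk = rr[win_index == k]
        if chunk.size < min_beats:
            logger.warning(
                "window %d (%.0f s): only %d beats, dropped", k, k * window_s, chunk.size
            )
            continue
        lfp = band_power(chunk, *LF_BAND, resample_hz=resample_hz)
        hfp = band_power(chunk, *HF_BAND, resample_hz=resample_hz)
        rows.append(
            {
                "window_start": k * window_s,
                "n_beats": chunk.size,
                "hr_mean": float(np.mean(instantaneous_hr(chunk))),
                "sdnn": sdnn(chunk, literal=literal),
                "rmssd": rmssd(chunk, literal=literal),
                "lfp": lfp,
                "hfp": hfp,
                "lf_hf": lfp / hfp if hfp > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
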