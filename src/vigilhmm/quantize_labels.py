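"""SDNN quantization into observation symbols and vigilance-state labelling.

Three vigilance levels (1 = low, 2 = medium, 3 = high) are linked to SDNN
through two cut points: windows with SDNN at or below ``t_low`` emit symbol
1, above ``t_high`` symbol 3, and symbol 2 in between (higher SDNN maps to
higher vigilance, matching the boxplot geometry of the calibration data).
The cut points can be derived from labelled SDNN samples as midpoints
between adjacent-level quartiles, and psychomotor-vigilance-task fastest-10%
reaction times map onto the state labels (<400 ms high, 400-500 ms medium,
>500 ms low).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdSet",
    "ThresholdDerivation",
    "DEFAULT_THRESHOLDS",
    "sdnn_to_symbol",
    "derive_thresholds",
    "pvt_to_state",
]


@dataclass(frozen=True)
class ThresholdSet:
    """SDNN cut points (ms): symbol 1/2 boundary and symbol 2/3 boundary."""

    t_low: float = 155.0
    t_high: float = 182.0

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError(f"need t_low < t_high, got ({self.t_low}, {self.t_high})")


#: packaged default used for reproducing the reference configuration
DEFAULT_THRESHOLDS = ThresholdSet(155.0, 182.0)


@dataclass(frozen=True)
class ThresholdDerivation:
    """Derived thresholds plus the quartile evidence behind them."""

    thresholds: ThresholdSet
    q3_low: float
    q1_medium: float
    q3_medium: float
    q1_high: float
    low_separable: bool
    high_separable: bool


def sdnn_to_symbol(sdnn_values, th: ThresholdSet = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Quantize SDNN values to symbols {1, 2, 3}.

    Values exactly equal to a threshold fall in the lower class.
    """
    v = np.asarray(sdnn_values, dtype=float)
    if v.size and not np.all(np.isfinite(v)):
        raise ValueError("SDNN values must be finite")
    return (np.digitize(v, [th.t_low, th.t_high], right=True) + 1).astype(np.int64)


def derive_thresholds(low, medium, high) -> ThresholdDerivation:
    """Derive SDNN cut points from labelled samples by the quartile rule.

    ``t_low`` is the midpoint of (Q3 of the low-level samples, Q1 of the
    medium-level samples); ``t_high`` the midpoint of (Q3 of medium, Q1 of
    high).  Quartiles use linear interpolation (the type-7 default).  When a
    quartile pair overlaps (Q3 of the lower level >= Q1 of the upper) the
    midpoint is still returned but the pair is flagged non-separable and a
    warning is emitted.
    """
    groups = [np.asarray(g, dtype=float) for g in (low, medium, high)]
    names = ("low", "medium", "high")
    for name, g in zip(names, groups):
        if g.size < 4:
            raise ValueError(f"need at least 4 samples per level, {name} has {g.size}")
    medians = [float(np.median(g)) for g in groups]
    if not medians[0] < medians[1] < medians[2]:
        raise ValueError(f"level medians must be ordered low < medium < high, got {medians}")

    q3_low = float(np.quantile(groups[0], 0.75))
    q1_med = float(np.quantile(groups[1], 0.25))
    q3_med = float(np.quantile(groups[1], 0.75))
    q1_high = float(np.quantile(groups[2], 0.25))

    low_sep = q3_low < q1_med
    high_sep = q3_med < q1_high
    if not low_sep:
        warnings.warn(
            f"low/medium quartiles overlap (Q3={q3_low} >= Q1={q1_med})", stacklevel=2
        )
    if not high_sep:
        warnings.warn(
            f"medium/high quartiles overlap (Q3={q3_med} >= Q1={q1_high})", stacklevel=2
        )
    th = ThresholdSet((q3_low + q1_med) / 2.0, (q3_med + q1_high) / 2.0)
    return ThresholdDerivation(th, q3_low, q1_med, q3_med, q1_high, low_sep, high_sep)


def pvt_to_state(fastest10_rt) -> np.ndarray | int:
    """Map PVT fastest-10% reaction time (ms) to a vigilance state label.

    rt < 400 -> 3 (high), 400 <= rt <= 500 -> 2 (medium), rt > 500 -> 1 (low).
    """
    rt = np.asarray(fastest10_rt, dtype=float)
    scalar = rt.ndim == 0
    rt = np.atleast_1d(rt)
    if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("reaction times must be finite and positive")
    state = np.where(rt < 400, 3, np.where(rt <= 500, 2, 1)).astype(np.int64)
    return int(state[0]) if scalar else state
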