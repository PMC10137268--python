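"""Scoring of predicted against recorded vigilance-state sequences.

Three metrics: accuracy (fraction of matching positions), Hamming distance
(count of mismatching positions) and mean absolute error over the
integer-coded state labels.  For states coded 1..N the metrics obey
``hamming / n <= mae <= (N - 1) * hamming / n`` and
``accuracy + hamming / n = 1``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "accuracy", "hamming", "mae", "evaluate"]


def _paired(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.ndim != 1 or truth.ndim != 1:
        raise ValueError("sequences must be one-dimensional")
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    if len(pred) == 0:
        raise ValueError("empty sequences")
    return pred, truth


def accuracy(pred, truth) -> float:
    """Fraction of positions where predicted and recorded states agree."""
    pred, truth = _paired(pred, truth)
    return float(np.mean(pred == truth))


def hamming(pred, truth) -> int:
    """Number of positions where two equal-length sequences differ."""
    pred, truth = _paired(pred, truth)
    return int(np.sum(pred != truth))


def mae(pred, truth) -> float:
    """Mean absolute error between integer-coded state labels."""
    pred, truth = _paired(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


@dataclass(frozen=True)
class EvalReport:
    """Scores for one (predicted, recorded) state-sequence pair."""

    accuracy: float
    hamming: int
    mae: float
    n: int

    @property
    def accuracy_pct(self) -> float:
        return self.accuracy * 100.0

    def to_dict(self) -> dict:
        """JSON-friendly report; percentages to 2 decimals, MAE to 4."""
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "accuracy_pct": round(self.accuracy_pct, 2),
            "hamming": self.hamming,
            "mae": round(self.mae, 4),
        }

    def __str__(self) -> str:
        return (
            f"n={self.n}  accuracy={self.accuracy_pct:.2f}%  "
            f"hamming={self.hamming}  mae={self.mae:.4f}"
        )


def evaluate(pred, truth) -> EvalReport:
    """Score a predicted state sequence against the recorded one."""
    pred, truth = _paired(pred, truth)
    return EvalReport(
        accuracy=accuracy(pred, truth),
        hamming=hamming(pred, truth),
        mae=mae(pred, truth),
        n=len(pred),
    )
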