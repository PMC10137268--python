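"""Configuration, file round-tripping and the end-to-end pipeline.

File formats are all plain text: RR series as single-column CSV with header
``rr_ms``; integer symbol/state sequences as whitespace-separated values,
one sequence per line; HMM parameters as JSON with keys ``N``, ``M``,
``pi``, ``A``, ``B``; feature tables as CSV; evaluation reports as JSON.

``run_pipeline`` chains the stages: (ECG ->) RR -> per-window HRV features
-> SDNN quantization -> Viterbi decoding against a model -> scoring against
recorded labels, writing intermediates when asked and wrapping stage
failures with the stage name.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg_preprocess, evaluation, hmm_core, hrv_features, quantize_labels
from .ecg_preprocess import ECGRecord, RRSeries
from .evaluation import EvalReport
from .hmm_core import DiscreteHMMParams
from .quantize_labels import ThresholdSet

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "read_rr_csv",
    "write_rr_csv",
    "read_ecg_csv",
    "read_sequences",
    "write_sequences",
    "read_model",
    "write_model",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings; the defaults reproduce the reference study
    configuration (N = M = 3, thresholds 155/182 ms, concatenated training).
    """

    fs: float = 100.0
    window_s: float = 60.0
    thresholds: ThresholdSet = ThresholdSet(155.0, 182.0)
    max_iter: int = 500
    tol: float = 1e-6
    concat: bool = True
    smoothing: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fs": self.fs,
            "window_s": self.window_s,
            "quantize": {"t_low": self.thresholds.t_low, "t_high": self.thresholds.t_high},
            "hmm": {
                "max_iter": self.max_iter,
                "tol": self.tol,
                "concat": self.concat,
                "smoothing": self.smoothing,
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        q = d.get("quantize", {})
        h = d.get("hmm", {})
        defaults = cls()
        return cls(
            fs=d.get("fs", defaults.fs),
            window_s=d.get("window_s", defaults.window_s),
            thresholds=ThresholdSet(
                q.get("t_low", defaults.thresholds.t_low),
                q.get("t_high", defaults.thresholds.t_high),
            ),
            max_iter=h.get("max_iter", defaults.max_iter),
            tol=h.get("tol", defaults.tol),
            concat=h.get("concat", defaults.concat),
            smoothing=h.get("smoothing", defaults.smoothing),
            seed=d.get("seed", defaults.seed),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_rr_csv(path) -> RRSeries:
    """Read a single-column CSV of RR intervals in milliseconds."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no RR intervals")
    col = "rr_ms" if "rr_ms" in df.columns else df.columns[0]
    return RRSeries(rr=df[col].to_numpy(dtype=float))


def write_rr_csv(rr: RRSeries, path) -> None:
    pd.DataFrame({"rr_ms": np.asarray(rr.rr if isinstance(rr, RRSeries) else rr)}).to_csv(
        path, index=False
    )


def read_ecg_csv(path, fs: float | None = None) -> ECGRecord:
    """Read an ECG trace: 1 column (voltage; ``fs`` required) or 2 columns
    (time in seconds, voltage; ``fs`` inferred from the time step)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty ECG file")
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        steps = np.diff(t)
        if len(steps) == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return ECGRecord(samples=v, fs=1.0 / steps[0], t0=float(t[0]))
    if fs is None:
        raise ValueError(f"{path}: single-column ECG requires a sampling rate")
    return ECGRecord(samples=df.iloc[:, 0].to_numpy(dtype=float), fs=fs)


def read_sequences(path) -> list[np.ndarray]:
    """Whitespace-separated integer sequences, one per line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append(np.array(line.split(), dtype=np.int64))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed sequence line") from e
    if not out:
        raise ValueError(f"{path}: no sequences found")
    return out


def write_sequences(sequences, path) -> None:
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(" ".join(str(int(v)) for v in seq) + "\n")


def read_model(path, atol: float = 1e-9) -> DiscreteHMMParams:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("pi", "A", "B"):
        if key not in d:
            raise ValueError(f"{path}: model file missing key {key!r}")
    return DiscreteHMMParams.from_dict(d, atol=atol)


def write_model(params: DiscreteHMMParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    rr: RRSeries | None = None
    features: pd.DataFrame | None = None
    symbols: np.ndarray | None = None
    states: np.ndarray | None = None
    report: EvalReport | None = None


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(name, str(e)) from e


def run_pipeline(
    ecg: ECGRecord | None = None,
    rr: RRSeries | None = None,
    config: PipelineConfig = PipelineConfig(),
    model: DiscreteHMMParams | None = None,
    labels=None,
    out_dir=None,
) -> PipelineResult:
    """Run preprocess -> features -> quantize -> decode -> evaluate.

    Exactly one of ``ecg`` or ``rr`` must be given.  Decoding needs
    ``model``; scoring needs ``labels`` (recorded states, one per analysis
    window) of the same length as the decoded sequence.  Intermediates are
    written into ``out_dir`` when provided.
    """
    if (ecg is None) == (rr is None):
        raise PipelineError("input", "provide exactly one of ecg or rr")
    result = PipelineResult()

    if ecg is not None:
        rr = _stage("ecg_preprocess", ecg_preprocess.ecg_to_rr, ecg)
        logger.info("ecg_preprocess: %d beats from %.0f s of ECG", len(rr), ecg.duration_s)
    result.rr = rr

    feats = _stage("hrv_features", hrv_features.window_features, rr, config.window_s)
    logger.info("hrv_features: %d windows of %.0f s", len(feats), config.window_s)
    if feats.empty:
        raise PipelineError("hrv_features", "no complete analysis windows in input")
    result.features = feats

    symbols = _stage(
        "quantize", quantize_labels.sdnn_to_symbol, feats["sdnn"].to_numpy(), config.thresholds
    )
    result.symbols = symbols

    if model is not None:
        result.states = _stage("decode", hmm_core.viterbi, model, symbols)
        if labels is not None:
            labels = np.asarray(labels, dtype=np.int64)
            if len(labels) != len(result.states):
                raise PipelineError(
                    "evaluate",
                    f"{len(labels)} labels but {len(result.states)} decoded windows",
                )
            result.report = _stage("evaluate", evaluation.evaluate, result.states, labels)
            logger.info("evaluate: %s", result.report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_rr_csv(rr, out / "rr.csv")
        feats.to_csv(out / "features.csv", index=False)
        write_sequences(symbols, out / "symbols.txt")
        if result.states is not None:
            write_sequences(result.states, out / "states_pred.txt")
        if result.report is not None:
            with open(out / "report.json", "w") as fh:
                json.dump(result.report.to_dict(), fh, indent=2)
                fh.write("\n")
    return result
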