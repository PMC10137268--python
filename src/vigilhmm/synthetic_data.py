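"""Seeded generators with known ground truth, plus packaged reference fixtures.

Three generators emulate the kind of recordings the vigilance model is
fitted to, each returning its generating truth so downstream stages can be
scored:

* ``sample_hmm`` draws (state, symbol) paths from a discrete HMM;
* ``synth_rr`` turns a state path into an RR-interval series whose per-state
  standard deviation straddles the SDNN quantization thresholds;
* ``synth_ecg`` renders an RR series as a template-QRS ECG trace with known
  R-peak sample positions.

``paper_fixtures`` loads the published worked-example sequences, trained
matrices and three-volunteer validation records shipped as plain-text
package data (integrity-checked against embedded SHA-256 digests).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .ecg_preprocess import ECGRecord, RRSeries
from .hmm_core import DiscreteHMMParams
from .quantize_labels import DEFAULT_THRESHOLDS, ThresholdSet

__all__ = [
    "SynthConfig",
    "DEFAULT_GENERATOR",
    "WELL_SEPARATED_GENERATOR",
    "sample_hmm",
    "synth_rr",
    "synth_ecg",
    "PaperFixtures",
    "VolunteerRecord",
    "paper_fixtures",
]

_FIXTURE_SHA256 = {
    "worked_example_sequences.txt": "0d9358d7c58d00f50f721fd1459f6b7efca2bf249a81f2c25c4b095fffba32c5",
    "reference_matrices.txt": "dac1899e50b9c5e8b80e43f13e3b0ee43fb3ca4670979a7caa2befa6022bf747",
    "validation_sequences.txt": "6eabeac8aadd3ff3a21ac254748061d27047c4d53dd7c7163d81a0df99f94a3a",
}

#: generating chain used by the default synthetic configuration: sticky
#: transitions (vigilance persists across minutes) and emissions that confuse
#: neighbouring levels more than distant ones.
DEFAULT_GENERATOR = DiscreteHMMParams(
    pi=np.full(3, 1.0 / 3.0),
    A=np.array([[0.70, 0.20, 0.10], [0.15, 0.70, 0.15], [0.10, 0.20, 0.70]]),
    B=np.array([[0.80, 0.15, 0.05], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]]),
)

#: well-separated chain for parameter-recovery simulations: each state puts
#: 95% of its emission mass on its own symbol, so the hidden states are
#: nearly observed and recovery error is dominated by transition-count
#: sampling noise rather than state ambiguity.
WELL_SEPARATED_GENERATOR = DiscreteHMMParams(
    pi=np.full(3, 1.0 / 3.0),
    A=np.array([[0.80, 0.15, 0.05], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]]),
    B=np.array([[0.95, 0.04, 0.01], [0.025, 0.95, 0.025], [0.01, 0.04, 0.95]]),
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic RR/ECG generators.

    Per-state RR standard deviations are chosen so the expected per-window
    SDNN of state 1 sits below the low threshold and that of state 3 above
    the high threshold, mirroring the boxplot geometry of the calibration
    data without reusing it.
    """

    params: DiscreteHMMParams = DEFAULT_GENERATOR
    rr_mean_ms: tuple[float, float, float] = (900.0, 900.0, 900.0)
    rr_sd_ms: tuple[float, float, float] = (80.0, 170.0, 220.0)
    fs: float = 100.0
    seed: int = 0
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if len(self.rr_mean_ms) != 3 or len(self.rr_sd_ms) != 3:
            raise ValueError("need RR mean and SD for each of the 3 states")
        if not (self.rr_sd_ms[0] < self.thresholds.t_low and self.rr_sd_ms[2] > self.thresholds.t_high):
            raise ValueError(
                "per-state RR SDs must straddle the thresholds "
                "(state 1 below t_low, state 3 above t_high)"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


def sample_hmm(params: DiscreteHMMParams, T: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (state, symbol) pair of length-T sequences (1-based) from lambda."""
    params.validate()
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = _as_rng(seed)
    N, M = params.N, params.M
    Q = np.empty(T, dtype=np.int64)
    O = np.empty(T, dtype=np.int64)
    state = rng.choice(N, p=params.pi)
    for t in range(T):
        if t > 0:
            state = rng.choice(N, p=params.A[state])
        Q[t] = state + 1
        O[t] = rng.choice(M, p=params.B[state]) + 1
    return Q, O


def synth_rr(
    state_seq,
    cfg: SynthConfig = SynthConfig(),
    beats_per_state: int | None = None,
    window_s: float = 60.0,
    rr_floor_ms: float = 300.0,
    rng=None,
) -> tuple[RRSeries, np.ndarray]:
    """RR series driven by a vigilance-state path, with per-window truth labels.

    Each state in ``state_seq`` governs one segment of beats drawn i.i.d.
    from a normal with that state's RR mean and SD (draws at or below
    ``rr_floor_ms`` are redrawn).  By default a segment is filled until it
    spans ``window_s`` seconds and then rescaled to that exact duration, so
    segment k coincides with analysis window k indefinitely; passing
    ``beats_per_state`` instead draws a fixed beat count per segment with no
    rescaling.

    Returns the RR series and the generating state per segment.
    """
    states = np.asarray(state_seq, dtype=np.int64)
    if states.ndim != 1 or states.size == 0:
        raise ValueError("state sequence must be a non-empty 1-D array")
    if np.any(states < 1) or np.any(states > 3):
        raise ValueError("states must lie in {1, 2, 3}")
    rng = _as_rng(cfg.seed if rng is None else rng)

    w_ms = window_s * 1000.0
    segments = []
    for s in states:
        mean, sd = cfg.rr_mean_ms[s - 1], cfg.rr_sd_ms[s - 1]
        if beats_per_state is not None:
            seg = _draw_positive(rng, mean, sd, beats_per_state, rr_floor_ms)
        else:
            n_guess = max(4, int(np.ceil(w_ms / max(mean - 3 * sd, rr_floor_ms))) + 8)
            seg = _draw_positive(rng, mean, sd, n_guess, rr_floor_ms)
            while seg.sum() < w_ms:
                seg = np.concatenate([seg, _draw_positive(rng, mean, sd, 8, rr_floor_ms)])
            cut = int(np.searchsorted(np.cumsum(seg), w_ms)) + 1
            seg = seg[:cut]
            seg = seg * (w_ms / seg.sum())
        segments.append(seg)
    return RRSeries(rr=np.concatenate(segments)), states.copy()


def _draw_positive(rng, mean, sd, n, floor_ms):
    out = mean + sd * rng.standard_normal(n)
    bad = out <= floor_ms
    while bad.any():
        out[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
        bad = out <= floor_ms
    return out


def synth_ecg(
    rr,
    fs: float = 500.0,
    snr_db: float | None = None,
    qrs_sigma_s: float = 0.01,
    rng=None,
) -> tuple[ECGRecord, np.ndarray]:
    """Template-QRS ECG for an RR series, with true R-peak sample indices.

    A narrow positive Gaussian pulse (peak 1, width ``qrs_sigma_s``) is
    placed at each cumulative beat time over a flat baseline; white Gaussian
    noise is added to reach ``snr_db`` (signal power over noise power), or
    none when ``snr_db`` is None.
    """
    if isinstance(rr, RRSeries):
        rr = rr.rr
    rr = np.asarray(rr, dtype=float)
    if fs < 50:
        raise ValueError("sampling rate must be at least 50 Hz")
    template_ms = 6 * qrs_sigma_s * 1000.0
    if rr.size and rr.min() < template_ms:
        raise ValueError(f"RR intervals shorter than the {template_ms:.0f} ms QRS template")

    peak_times_ms = np.concatenate([[0.0], np.cumsum(rr)])
    true_idx = np.round(peak_times_ms * fs / 1000.0).astype(np.int64)
    n = int(true_idx[-1] + round(0.3 * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = int(np.ceil(4 * qrs_sigma_s * fs))
    for tp, ip in zip(peak_times_ms / 1000.0, true_idx):
        lo, hi = max(0, ip - half), min(n, ip + half + 1)
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tp) / qrs_sigma_s) ** 2)
    if snr_db is not None:
        p_sig = float(np.mean(x**2))
        sigma = np.sqrt(p_sig / 10 ** (snr_db / 10.0))
        x = x + sigma * _as_rng(rng).standard_normal(n)
    return ECGRecord(samples=x, fs=fs), true_idx


# ---------------------------------------------------------------------------
# packaged reference fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VolunteerRecord:
    """One validation volunteer: observations, recorded and predicted states."""

    observations: np.ndarray
    recorded: np.ndarray
    predicted: np.ndarray


@dataclass(frozen=True)
class PaperFixtures:
    """Published worked-example and validation data as typed arrays."""

    O30: np.ndarray
    Q30: np.ndarray
    B_init: np.ndarray
    A_hat: np.ndarray
    B_hat: np.ndarray
    volunteers: dict[int, VolunteerRecord] = field(default_factory=dict)

    def hat_params(self, pi=None) -> DiscreteHMMParams:
        """Trained model from the published A_hat/B_hat.

        Rows are renormalized to sum exactly to 1 (the printed values carry
        rounding of up to 1e-4 per row).  The trained initial distribution
        was never published; ``pi`` defaults to uniform.
        """
        A = self.A_hat / self.A_hat.sum(axis=1, keepdims=True)
        B = self.B_hat / self.B_hat.sum(axis=1, keepdims=True)
        if pi is None:
            pi = np.full(3, 1.0 / 3.0)
        return DiscreteHMMParams(pi=pi, A=A, B=B).validate()


def _read_fixture_text(name: str) -> list[str]:
    path = resources.files("vigilhmm.data").joinpath(name)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(f"fixture {name} corrupted (sha256 {digest})")
    lines = []
    for line in raw.decode().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            lines.append(line)
    return lines


def paper_fixtures() -> PaperFixtures:
    """Load the packaged reference sequences and matrices."""
    seq_lines = _read_fixture_text("worked_example_sequences.txt")
    seqs = {parts[0]: np.array(parts[1:], dtype=np.int64) for parts in (l.split() for l in seq_lines)}

    mats: dict[str, list[list[float]]] = {}
    for line in _read_fixture_text("reference_matrices.txt"):
        parts = line.split()
        mats.setdefault(parts[0], []).append([float(v) for v in parts[1:]])

    vols: dict[int, dict[str, np.ndarray]] = {}
    for line in _read_fixture_text("validation_sequences.txt"):
        parts = line.split()
        vid = int(parts[0][1:])
        vols.setdefault(vid, {})[parts[1]] = np.array(parts[2:], dtype=np.int64)

    volunteers = {
        vid: VolunteerRecord(
            observations=d["obs"], recorded=d["rec"], predicted=d["pred"]
        )
        for vid, d in sorted(vols.items())
    }
    return PaperFixtures(
        O30=seqs["O"],
        Q30=seqs["Q"],
        B_init=np.array(mats["B_init"]),
        A_hat=np.array(mats["A_hat"]),
        B_hat=np.array(mats["B_hat"]),
        volunteers=volunteers,
    )
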