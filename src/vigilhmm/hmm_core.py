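"""Discrete-emission hidden Markov model: initialization, training, decoding.

The model is the classic triple lambda = (pi, A, B): initial state
distribution, N x N state-transition matrix and N x M emission matrix over a
finite symbol alphabet.  In the vigilance application N = M = 3: hidden
states are vigilance levels (1 low, 2 medium, 3 high) and symbols are
quantized SDNN levels.

Initialization follows the left-right convention (pi = (1, 0, ..., 0)), a
uniform transition matrix, and a supervised count-based emission matrix from
paired symbol/state sequences.  Training is Baum-Welch (EM) with per-step
scaling constants; decoding is Viterbi in log space with ties broken toward
the lowest state index.  Sequences are 1-based (values in {1..M} / {1..N})
at the API surface, matching how they are written in files and reports;
indices are 0-based internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscreteHMMParams",
    "TrainingTrace",
    "init_pi_leftright",
    "init_A_uniform",
    "init_B_supervised",
    "forward_loglik",
    "viterbi",
    "baum_welch",
]

_STOCHASTIC_ATOL = 1e-9


@dataclass(frozen=True)
class DiscreteHMMParams:
    """Parameter triple (pi, A, B) of a discrete-emission HMM.

    ``A[i, j]`` is P(next state j | current state i); ``B[i, k]`` is
    P(symbol k | state i).  All rows are probability distributions.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))

    @property
    def N(self) -> int:
        return len(self.pi)

    @property
    def M(self) -> int:
        return self.B.shape[1]

    def validate(self, atol: float = _STOCHASTIC_ATOL) -> "DiscreteHMMParams":
        """Check shapes, entry ranges and row-stochasticity within ``atol``."""
        N = self.N
        if self.A.shape != (N, N):
            raise ValueError(f"A must be {N}x{N}, got {self.A.shape}")
        if self.B.ndim != 2 or self.B.shape[0] != N:
            raise ValueError(f"B must have {N} rows, got {self.B.shape}")
        for name, arr in (("pi", self.pi[None, :]), ("A", self.A), ("B", self.B)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise ValueError(f"{name} entries outside [0, 1]")
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=atol, rtol=0):
                raise ValueError(f"rows of {name} must sum to 1, got {sums}")
        return self

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "M": self.M,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict, atol: float = _STOCHASTIC_ATOL) -> "DiscreteHMMParams":
        params = cls(pi=d["pi"], A=d["A"], B=d["B"])
        if "N" in d and d["N"] != params.N:
            raise ValueError(f"declared N={d['N']} but pi has length {params.N}")
        if "M" in d and d["M"] != params.M:
            raise ValueError(f"declared M={d['M']} but B has {params.M} columns")
        return params.validate(atol=atol)


@dataclass
class TrainingTrace:
    """Per-iteration log-likelihood record of a Baum-Welch run."""

    log_likelihood: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def init_pi_leftright(N: int) -> np.ndarray:
    """Left-right initial distribution: probability 1 on the first state."""
    if N < 1:
        raise ValueError("N must be >= 1")
    pi = np.zeros(N)
    pi[0] = 1.0
    return pi


def init_A_uniform(N: int) -> np.ndarray:
    """Uniform transition matrix: every state may move to every state, 1/N each."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return np.full((N, N), 1.0 / N)


def _check_sequence(seq, M: int, name: str = "sequence") -> np.ndarray:
    seq = np.asarray(seq, dtype=np.int64)
    if seq.ndim != 1 or seq.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D integer sequence")
    if np.any(seq < 1) or np.any(seq > M):
        raise ValueError(f"{name} values must lie in 1..{M}")
    return seq


def init_B_supervised(O, Q, N: int = 3, M: int = 3, smoothing: float = 0.0) -> np.ndarray:
    """Count-based emission matrix from a paired symbol/state record.

    ``B[i, j] = (#{t: Q_t = i+1 and O_t = j+1} + smoothing) /
    (#{t: Q_t = i+1} + M * smoothing)``.  A state never observed in ``Q``
    receives the uniform row.
    """
    O = _check_sequence(O, M, "observation sequence")
    Q = _check_sequence(Q, N, "state sequence")
    if len(O) != len(Q):
        raise ValueError(f"length mismatch: {len(O)} observations vs {len(Q)} states")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    counts = np.zeros((N, M))
    np.add.at(counts, (Q - 1, O - 1), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    B = np.empty((N, M))
    seen = totals[:, 0] > 0
    with np.errstate(invalid="ignore"):
        B[seen] = (counts[seen] + smoothing) / (totals[seen] + M * smoothing)
    B[~seen] = 1.0 / M
    return B


def _scaled_forward(params: DiscreteHMMParams, o: np.ndarray):
    """Scaled forward pass. Returns (alpha_hat, scales) or None if impossible."""
    T = len(o)
    Bo = params.B[:, o]  # N x T
    alpha = np.empty((T, params.N))
    scales = np.empty(T)
    a = params.pi * Bo[:, 0]
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ params.A) * Bo[:, t]
        c = a.sum()
        if c == 0.0:
            return None
        scales[t] = c
        alpha[t] = a / c
    return alpha, scales


def forward_loglik(params: DiscreteHMMParams, O) -> float:
    """log P(O | lambda) via the scaled forward algorithm.

    Returns ``-inf`` when the observation sequence is impossible under the
    model parameters.
    """
    params.validate()
    o = _check_sequence(O, params.M, "observation sequence") - 1
    res = _scaled_forward(params, o)
    if res is None:
        return float("-inf")
    _, scales = res
    return float(np.sum(np.log(scales)))


def viterbi(params: DiscreteHMMParams, O, leftright_pi: bool = False) -> np.ndarray:
    """Most probable hidden-state path (1-based) for an observation sequence.

    Dynamic programming in log space; ties are broken toward the lowest state
    index at every step.  ``leftright_pi=True`` decodes with the left-right
    initial distribution (1, 0, ..., 0) instead of the model's own pi.
    """
    params.validate()
    o = _check_sequence(O, params.M, "observation sequence") - 1
    T, N = len(o), params.N
    pi = init_pi_leftright(N) if leftright_pi else params.pi
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_A = np.log(params.A)
        log_Bo = np.log(params.B[:, o])

    delta = log_pi + log_Bo[:, 0]
    psi = np.empty((T, N), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + log_A  # scores[i, j]: from i into j
        psi[t] = np.argmax(scores, axis=0)  # first max -> lowest index
        delta = scores[psi[t], np.arange(N)] + log_Bo[:, t]
    if np.all(np.isinf(delta)):
        raise ValueError("observation sequence impossible under the model")

    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path + 1


def baum_welch(
    params0: DiscreteHMMParams,
    sequences,
    max_iter: int = 500,
    tol: float = 1e-6,
    concat: bool = False,
    update_pi: bool = True,
    floor: float = 1e-12,
) -> tuple[DiscreteHMMParams, TrainingTrace]:
    """Baum-Welch (EM) re-estimation of (pi, A, B) from symbol sequences.

    ``sequences`` is one sequence or a list of 1-based symbol sequences.
    With ``concat=True`` the sequences are joined into a single stream before
    training (the chain runs straight through the joins); the default treats
    them independently, restarting the initial distribution at each.

    Re-estimated rows are floored at ``floor`` before renormalization so a
    finite sample cannot produce absorbing zeros.  Iteration stops at
    ``max_iter`` or when the total log-likelihood improves by less than
    ``tol``.  The recorded trace log-likelihoods are evaluated at the
    parameters entering each iteration and are non-decreasing.
    """
    params0.validate()
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    elif sequences and isinstance(sequences[0], (int, np.integer)):
        sequences = [sequences]
    seqs = [_check_sequence(s, params0.M, "observation sequence") - 1 for s in sequences]
    if not seqs:
        raise ValueError("empty training set")
    if concat:
        seqs = [np.concatenate(seqs)]

    N, M = params0.N, params0.M
    pi, A, B = params0.pi.copy(), params0.A.copy(), params0.B.copy()
    trace = TrainingTrace()

    for it in range(max_iter):
        params = DiscreteHMMParams(pi, A, B)
        ll = 0.0
        A_num = np.zeros((N, N))
        B_num = np.zeros((N, M))
        pi_acc = np.zeros(N)
        for o in seqs:
            res = _scaled_forward(params, o)
            if res is None:
                raise ValueError("training sequence impossible under current parameters")
            alpha, scales = res
            ll += float(np.sum(np.log(scales)))
            T = len(o)
            Bo = B[:, o]
            beta = np.empty((T, N))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[t] = (A @ (Bo[:, t + 1] * beta[t + 1])) / scales[t + 1]
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            if T > 1:
                # xi summed over t in one shot; row-normalizing the sum later
                # equals the usual sum-gamma denominator
                A_num += A * np.einsum(
                    "ti,tj->ij", alpha[:-1] / scales[1:, None], Bo[:, 1:].T * beta[1:]
                )
            np.add.at(B_num.T, o, gamma)
            pi_acc += gamma[0]

        trace.log_likelihood.append(ll)
        trace.iterations_run = it + 1
        if it > 0 and ll - trace.log_likelihood[-2] < tol:
            trace.converged = True
            break

        A = np.maximum(A_num, floor)
        A /= A.sum(axis=1, keepdims=True)
        B = np.maximum(B_num, floor)
        B /= B.sum(axis=1, keepdims=True)
        if update_pi:
            pi = np.maximum(pi_acc / len(seqs), floor)
            pi /= pi.sum()

    return DiscreteHMMParams(pi, A, B).validate(), trace
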