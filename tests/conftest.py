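"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (exhaustive path enumeration, plain
loops) and independent of the package's vectorized code paths so they can
serve as ground truth in tests.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from vigilhmm import DiscreteHMMParams, paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_params(rng: np.random.Generator, N: int = 3, M: int = 3) -> DiscreteHMMParams:
    """A random valid parameter triple drawn from Dirichlet rows."""
    return DiscreteHMMParams(
        pi=rng.dirichlet(np.ones(N)),
        A=rng.dirichlet(np.ones(N), size=N),
        B=rng.dirichlet(np.ones(M), size=N),
    )


def enumerate_likelihood(params: DiscreteHMMParams, O) -> float:
    """P(O | lambda) by brute-force summation over every hidden path."""
    o = np.asarray(O, dtype=int) - 1
    total = 0.0
    for path in itertools.product(range(params.N), repeat=len(o)):
        p = params.pi[path[0]] * params.B[path[0], o[0]]
        for t in range(1, len(o)):
            p *= params.A[path[t - 1], path[t]] * params.B[path[t], o[t]]
        total += p
    return total


def enumerate_best_path(params: DiscreteHMMParams, O):
    """(probability, path) of the most probable hidden path, enumerated.

    Ties are broken toward the lexicographically smallest path, matching the
    decoder's stated convention.
    """
    o = np.asarray(O, dtype=int) - 1
    best_p, best_path = -1.0, None
    for path in itertools.product(range(params.N), repeat=len(o)):
        p = params.pi[path[0]] * params.B[path[0], o[0]]
        for t in range(1, len(o)):
            p *= params.A[path[t - 1], path[t]] * params.B[path[t], o[t]]
        if p > best_p:
            best_p, best_path = p, path
    return best_p, np.asarray(best_path) + 1


def path_log_prob(params: DiscreteHMMParams, O, path) -> float:
    """Joint log probability of one (path, observations) pair."""
    o = np.asarray(O, dtype=int) - 1
    s = np.asarray(path, dtype=int) - 1
    with np.errstate(divide="ignore"):
        lp = np.log(params.pi[s[0]]) + np.log(params.B[s[0], o[0]])
        for t in range(1, len(o)):
            lp += np.log(params.A[s[t - 1], s[t]]) + np.log(params.B[s[t], o[t]])
    return float(lp)
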