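"""Discrete HMM: initialization, likelihood, decoding, training."""
import numpy as np
import pytest

from vigilhmm import (
    DiscreteHMMParams,
    baum_welch,
    forward_loglik,
    init_A_uniform,
    init_B_supervised,
    init_pi_leftright,
    sample_hmm,
    viterbi,
)

from conftest import (
    enumerate_best_path,
    enumerate_likelihood,
    path_log_prob,
    random_params,
)


class TestInitialization:
    @pytest.mark.parametrize("N", [1, 3, 4])
    def test_leftright_pi_starts_in_first_state(self, N):
        pi = init_pi_leftright(N)
        assert pi[0] == 1.0 and pi.sum() == 1.0 and np.all(pi[1:] == 0.0)

    @pytest.mark.parametrize("N", [1, 2, 3])
    def test_uniform_transitions(self, N):
        np.testing.assert_allclose(init_A_uniform(N), np.full((N, N), 1.0 / N))

    def test_invalid_state_count_rejected(self):
        with pytest.raises(ValueError):
            init_pi_leftright(0)


class TestSupervisedEmissions:
    def test_worked_example_counts(self, fixtures):
        """The published length-30 record gives b11 = 3/8 (printed 0.38),
        b12 = 2/8 and b13 = 3/8."""
        B = init_B_supervised(fixtures.O30, fixtures.Q30, 3, 3, smoothing=0.0)
        assert B[0, 0] == pytest.approx(3 / 8)
        assert B[0, 1] == pytest.approx(2 / 8)
        assert B[0, 2] == pytest.approx(3 / 8)
        np.testing.assert_allclose(B.sum(axis=1), 1.0)

    def test_unseen_states_get_uniform_row(self):
        B = init_B_supervised([2, 2, 2], [1, 1, 1], 3, 3, smoothing=0.0)
        np.testing.assert_allclose(B[0], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(B[1], 1 / 3)
        np.testing.assert_allclose(B[2], 1 / 3)

    def test_smoothing_pseudocounts(self):
        B = init_B_supervised([1, 1], [1, 1], 2, 2, smoothing=1.0)
        np.testing.assert_allclose(B[0], [3 / 4, 1 / 4])

    def test_mismatched_or_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            init_B_supervised([1, 2], [1], 3, 3)
        with pytest.raises(ValueError):
            init_B_supervised([1, 4], [1, 1], 3, 3)


class TestForward:
    def test_uniform_emissions_make_states_irrelevant(self, rng):
        T = 9
        params = DiscreteHMMParams(
            pi=init_pi_leftright(3), A=rng.dirichlet(np.ones(3), 3), B=np.full((3, 3), 1 / 3)
        )
        O = rng.integers(1, 4, T)
        assert forward_loglik(params, O) == pytest.approx(T * np.log(1 / 3))

    def test_single_state_chain_collapses_to_product(self):
        params = DiscreteHMMParams(pi=[1.0], A=[[1.0]], B=[[0.2, 0.5, 0.3]])
        assert forward_loglik(params, [2, 2, 1]) == pytest.approx(np.log(0.5 * 0.5 * 0.2))

    def test_impossible_observation_is_minus_inf(self):
        params = DiscreteHMMParams(
            pi=[1.0, 0.0], A=[[0.5, 0.5], [0.5, 0.5]], B=[[1.0, 0.0], [1.0, 0.0]]
        )
        assert forward_loglik(params, [2]) == -np.inf

    def test_matches_exhaustive_enumeration(self, rng):
        """Scaled forward equals brute-force path summation on 100 random
        instances with N <= 3, T <= 7."""
        for _ in range(100):
            N = int(rng.integers(1, 4))
            M = int(rng.integers(2, 4))
            T = int(rng.integers(1, 8))
            params = random_params(rng, N, M)
            O = rng.integers(1, M + 1, T)
            expected = np.log(enumerate_likelihood(params, O))
            assert forward_loglik(params, O) == pytest.approx(expected, rel=1e-10)

    def test_invalid_rows_rejected(self):
        bad = DiscreteHMMParams(pi=[0.5, 0.4], A=np.eye(2), B=np.eye(2))
        with pytest.raises(ValueError):
            forward_loglik(bad, [1])


class TestViterbi:
    def test_identity_emissions_pin_states_to_symbols(self, rng):
        params = DiscreteHMMParams(pi=np.full(3, 1 / 3), A=init_A_uniform(3), B=np.eye(3))
        O = rng.integers(1, 4, 15)
        np.testing.assert_array_equal(viterbi(params, O), O)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            params = random_params(rng, 3, 3)
            O = rng.integers(1, 4, 6)
            best_p, best_path = enumerate_best_path(params, O)
            path = viterbi(params, O)
            assert path_log_prob(params, O, path) == pytest.approx(
                np.log(best_p), rel=1e-10
            )
            np.testing.assert_array_equal(path, best_path)

    def test_exact_ties_resolve_to_lowest_state(self):
        # fully symmetric model: every path has equal probability
        params = DiscreteHMMParams(
            pi=np.full(2, 0.5), A=np.full((2, 2), 0.5), B=np.full((2, 2), 0.5)
        )
        np.testing.assert_array_equal(viterbi(params, [1, 2, 1]), [1, 1, 1])

    def test_beats_random_alternative_paths(self, rng):
        for _ in range(3):
            params = random_params(rng, 3, 3)
            _, O = sample_hmm(params, 20, seed=rng)
            lp_star = path_log_prob(params, O, viterbi(params, O))
            for _ in range(1000):
                alt = rng.integers(1, 4, len(O))
                assert lp_star >= path_log_prob(params, O, alt) - 1e-12

    def test_impossible_sequence_raises(self):
        params = DiscreteHMMParams(
            pi=[1.0, 0.0], A=[[1.0, 0.0], [0.0, 1.0]], B=[[1.0, 0.0], [1.0, 0.0]]
        )
        with pytest.raises(ValueError):
            viterbi(params, [2])


class TestBaumWelch:
    def test_one_em_step_matches_hand_computation(self):
        """Single re-estimation on an N=2, M=2, T=3 case against the
        textbook formulas evaluated with plain unscaled loops."""
        pi = np.array([0.6, 0.4])
        A = np.array([[0.7, 0.3], [0.4, 0.6]])
        B = np.array([[0.8, 0.2], [0.3, 0.7]])
        O = np.array([1, 2, 1])
        o = O - 1
        T, N = 3, 2

        alpha = np.zeros((T, N))
        alpha[0] = pi * B[:, o[0]]
        for t in range(1, T):
            for j in range(N):
                alpha[t, j] = sum(alpha[t - 1, i] * A[i, j] for i in range(N)) * B[j, o[t]]
        beta = np.ones((T, N))
        for t in range(T - 2, -1, -1):
            for i in range(N):
                beta[t, i] = sum(
                    A[i, j] * B[j, o[t + 1]] * beta[t + 1, j] for j in range(N)
                )
        P = alpha[-1].sum()
        gamma = alpha * beta / P
        xi = np.zeros((T - 1, N, N))
        for t in range(T - 1):
            for i in range(N):
                for j in range(N):
                    xi[t, i, j] = alpha[t, i] * A[i, j] * B[j, o[t + 1]] * beta[t + 1, j] / P
        A_hand = xi.sum(axis=0) / gamma[:-1].sum(axis=0)[:, None]
        B_hand = np.zeros((N, 2))
        for j in range(2):
            B_hand[:, j] = gamma[o == j].sum(axis=0)
        B_hand /= gamma.sum(axis=0)[:, None]
        pi_hand = gamma[0]

        fitted, trace = baum_welch(
            DiscreteHMMParams(pi, A, B), O, max_iter=1, floor=0.0
        )
        np.testing.assert_allclose(fitted.A, A_hand, atol=1e-12)
        np.testing.assert_allclose(fitted.B, B_hand, atol=1e-12)
        np.testing.assert_allclose(fitted.pi, pi_hand, atol=1e-12)
        assert trace.log_likelihood[0] == pytest.approx(np.log(P), rel=1e-12)

    def test_loglik_nondecreasing_and_rows_stochastic(self, rng):
        Q, O = sample_hmm(random_params(rng, 3, 3), 200, seed=rng)
        for _ in range(3):
            p0 = random_params(rng, 3, 3)
            fitted, trace = baum_welch(p0, O, max_iter=60)
            ll = np.asarray(trace.log_likelihood)
            assert np.all(np.diff(ll) >= -1e-8)
            fitted.validate()

    def test_repeated_symbol_collapses_emissions(self, rng):
        seqs = [np.full(40, 2, dtype=np.int64) for _ in range(3)]
        p0 = random_params(rng, 3, 3)
        fitted, _ = baum_welch(p0, seqs, max_iter=50)
        assert np.all(fitted.B[:, 1] > 0.999)

    def test_concat_vs_per_sequence_modes_differ_on_multiseq(self, rng):
        gen = random_params(rng, 3, 3)
        seqs = [sample_hmm(gen, 60, seed=rng)[1] for _ in range(4)]
        p0 = random_params(rng, 3, 3)
        f_cat, _ = baum_welch(p0, seqs, max_iter=20, concat=True)
        f_sep, _ = baum_welch(p0, seqs, max_iter=20, concat=False)
        assert not np.allclose(f_cat.A, f_sep.A)

    def test_empty_training_set_rejected(self, rng):
        with pytest.raises(ValueError):
            baum_welch(random_params(rng, 3, 3), [])


class TestAgainstHmmlearn:
    """Cross-checks against an independent HMM library."""

    def test_forward_loglik_agrees(self, rng):
        hmm = pytest.importorskip("hmmlearn.hmm")
        for _ in range(10):
            params = random_params(rng, 3, 3)
            _, O = sample_hmm(params, 50, seed=rng)
            model = hmm.CategoricalHMM(n_components=3)
            model.startprob_ = params.pi
            model.transmat_ = params.A
            model.emissionprob_ = params.B
            theirs = model.score((O - 1).reshape(-1, 1))
            assert forward_loglik(params, O) == pytest.approx(theirs, rel=1e-10)

    def test_viterbi_path_agrees(self, rng):
        hmm = pytest.importorskip("hmmlearn.hmm")
        params = random_params(rng, 3, 3)
        _, O = sample_hmm(params, 80, seed=rng)
        model = hmm.CategoricalHMM(n_components=3)
        model.startprob_ = params.pi
        model.transmat_ = params.A
        model.emissionprob_ = params.B
        lp, their_path = model.decode((O - 1).reshape(-1, 1))
        ours = viterbi(params, O)
        # paths may differ only on exact ties; compare probabilities
        assert path_log_prob(params, O, ours) == pytest.approx(lp, rel=1e-10)


class TestModelSerialization:
    def test_dict_roundtrip(self, rng):
        params = random_params(rng, 3, 3)
        again = DiscreteHMMParams.from_dict(params.to_dict())
        np.testing.assert_allclose(again.A, params.A, atol=1e-12)

    def test_declared_sizes_checked(self, rng):
        d = random_params(rng, 3, 3).to_dict()
        d["N"] = 4
        with pytest.raises(ValueError):
            DiscreteHMMParams.from_dict(d)
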