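"""Discrete HMM: scaled recursions checked against exhaustive path enumeration.

For tiny models (N <= 3 states, M <= 3 symbols, T <= 6 steps) every state
path can be enumerated, giving exact likelihoods, posteriors and best
paths against which the dynamic-programming implementations are verified.
hmmlearn serves as an additional independent cross-check of the forward
likelihood.
"""

import itertools

import numpy as np
import pytest

from wristhar.hmm import (
    HmmParams,
    backward,
    baum_welch,
    emission_from_confusion,
    estimate_supervised,
    forward,
    posteriors,
    random_params,
    viterbi,
)

# ---------------------------------------------------------------- oracles


def path_probability(params, path, obs):
    p = params.pi[path[0]] * params.B[path[0], obs[0]]
    for t in range(1, len(obs)):
        p *= params.A[path[t - 1], path[t]] * params.B[path[t], obs[t]]
    return p


def enumerate_likelihood(params, obs):
    n, t = params.n_states, len(obs)
    return sum(
        path_probability(params, path, obs)
        for path in itertools.product(range(n), repeat=t)
    )


def enumerate_gamma(params, obs):
    n, t_len = params.n_states, len(obs)
    gamma = np.zeros((t_len, n))
    for path in itertools.product(range(n), repeat=t_len):
        p = path_probability(params, path, obs)
        for t, s in enumerate(path):
            gamma[t, s] += p
    return gamma / gamma.sum(axis=1, keepdims=True)


def enumerate_best_path(params, obs):
    n, t_len = params.n_states, len(obs)
    best, best_p, second_p = None, -1.0, -1.0
    for path in itertools.product(range(n), repeat=t_len):
        p = path_probability(params, path, obs)
        if p > best_p:
            best, best_p, second_p = path, p, best_p
        elif p > second_p:
            second_p = p
    return np.array(best), best_p, second_p


def assert_viterbi_matches_enumeration(params, obs):
    """The decoded path attains the enumerated maximum probability; when
    that maximum is unique (no floating-point tie) the paths are equal."""
    best, best_p, second_p = enumerate_best_path(params, obs)
    path, logp = viterbi(params, obs)
    assert logp == pytest.approx(np.log(best_p), abs=1e-8)
    assert path_probability(params, path, obs) == pytest.approx(best_p, rel=1e-9)
    if second_p < best_p * (1 - 1e-9):
        np.testing.assert_array_equal(path, best)


def random_fixture(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 4))
    m = int(rng.integers(1, 4))
    t = int(rng.integers(1, 7))
    params = random_params(n, m, rng)
    obs = rng.integers(0, m, size=t)
    return params, obs


# ------------------------------------------------------------------ tests


class TestForward:
    def test_single_state_closed_form(self, rng):
        b = np.array([[0.2, 0.5, 0.3]])
        params = HmmParams([1.0], [[1.0]], b)
        obs = rng.integers(0, 3, size=20)
        res = forward(params, obs)
        assert res.log_likelihood == pytest.approx(np.sum(np.log(b[0, obs])))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration(self, seed):
        params, obs = random_fixture(seed)
        res = forward(params, obs)
        assert res.log_likelihood == pytest.approx(
            np.log(enumerate_likelihood(params, obs)), abs=1e-10
        )

    def test_deterministic_chain_probability_one(self):
        params = HmmParams([1.0, 0.0], np.eye(2), np.eye(2))
        res = forward(params, [0, 0, 0])
        assert res.log_likelihood == pytest.approx(0.0)
        assert not res.impossible

    def test_impossible_sequence_flagged_not_raised(self):
        params = HmmParams([1.0, 0.0], np.eye(2), np.eye(2))
        res = forward(params, [0, 1, 0])  # state 0 can never emit symbol 1
        assert res.impossible and res.log_likelihood == -np.inf

    def test_out_of_range_symbol_rejected(self):
        params = HmmParams([1.0], [[1.0]], [[0.5, 0.5]])
        with pytest.raises(ValueError, match=r"\[0, 2\)"):
            forward(params, [0, 2])

    def test_matches_hmmlearn(self, rng):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        params = random_params(3, 4, rng)
        obs = rng.integers(0, 4, size=40)
        model = hmmlearn_hmm.CategoricalHMM(n_components=3)
        model.startprob_ = params.pi
        model.transmat_ = params.A
        model.emissionprob_ = params.B
        ref = model.score(obs.reshape(-1, 1))
        assert forward(params, obs).log_likelihood == pytest.approx(ref, abs=1e-8)


class TestBackward:
    def test_final_row_is_ones(self, rng):
        params = random_params(3, 3, rng)
        beta = backward(params, rng.integers(0, 3, size=8))
        np.testing.assert_array_equal(beta[-1], 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_alpha_beta_product_constant_in_t(self, seed):
        """sum_i alpha_t(i) beta_t(i) is t-invariant (and 1 in scaled form)."""
        params, obs = random_fixture(seed)
        if forward(params, obs).impossible:
            pytest.skip("fixture produced an impossible sequence")
        res = posteriors(params, obs)
        prod = (res.alpha * res.beta).sum(axis=1)
        np.testing.assert_allclose(prod, 1.0, atol=1e-10)

    def test_single_state_beta_closed_form(self):
        b = np.array([[0.3, 0.7]])
        params = HmmParams([1.0], [[1.0]], b)
        obs = np.array([0, 1, 1])
        beta = backward(params, obs)
        # unscaled beta_t = prod_{s>t} b(o_s); scaled by the forward scales
        res = forward(params, obs)
        unscaled = np.array([b[0, 1] * b[0, 1], b[0, 1], 1.0])
        rescale = np.array(
            [np.prod(res.scales[t + 1 :]) for t in range(3)]
        )
        np.testing.assert_allclose(beta[:, 0] * rescale, unscaled, atol=1e-12)


class TestPosteriors:
    def test_gamma_one_hot_for_identity_model(self):
        params = HmmParams([0.5, 0.5], np.full((2, 2), 0.5), np.eye(2))
        obs = np.array([0, 1, 1, 0])
        res = posteriors(params, obs)
        np.testing.assert_allclose(res.gamma, np.eye(2)[obs], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_normalized(self, seed):
        params, obs = random_fixture(seed)
        res = posteriors(params, obs)
        np.testing.assert_allclose(res.gamma.sum(axis=1), 1.0, atol=1e-10)
        if res.xi.shape[0]:
            np.testing.assert_allclose(res.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_gamma_matches_enumeration(self, seed):
        params, obs = random_fixture(seed)
        res = posteriors(params, obs)
        np.testing.assert_allclose(
            res.gamma, enumerate_gamma(params, obs), atol=1e-10
        )


class TestViterbi:
    def test_identity_model_echoes_observations(self):
        params = HmmParams([1.0, 0.0], np.eye(2), np.eye(2))
        path, logp = viterbi(params, [0, 0, 0])
        np.testing.assert_array_equal(path, [0, 0, 0])
        assert logp == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumerated_argmax(self, seed):
        params, obs = random_fixture(seed)
        assert_viterbi_matches_enumeration(params, obs)

    def test_fully_symmetric_ties_break_to_state_zero(self):
        params = HmmParams(
            [0.5, 0.5], np.full((2, 2), 0.5), np.full((2, 2), 0.5)
        )
        path, _ = viterbi(params, [0, 1, 0, 1])
        np.testing.assert_array_equal(path, 0)

    def test_path_probability_bounded_by_total(self, rng):
        for seed in range(5):
            params, obs = random_fixture(seed + 100)
            total = forward(params, obs).log_likelihood
            _, logp = viterbi(params, obs)
            assert logp <= total + 1e-10

    def test_impossible_path_returns_minus_inf(self):
        params = HmmParams([1.0, 0.0], np.eye(2), np.eye(2))
        path, logp = viterbi(params, [0, 1])
        assert logp == -np.inf


class TestBaumWelch:
    def test_loglik_non_decreasing_and_recovers_transitions(self):
        """Parameter recovery on 5,000 symbols from a diagonal-dominant
        2-state chain, entrywise within 0.05 after label permutation."""
        truth = HmmParams(
            [0.6, 0.4], [[0.92, 0.08], [0.12, 0.88]], [[0.85, 0.15], [0.1, 0.9]]
        )
        rng = np.random.default_rng(0)
        states = np.zeros(5000, dtype=int)
        states[0] = rng.choice(2, p=truth.pi)
        for t in range(1, 5000):
            states[t] = rng.choice(2, p=truth.A[states[t - 1]])
        obs = np.array([rng.choice(2, p=truth.B[s]) for s in states])

        est, ll = baum_welch([obs], 2, 2, init=1, max_iter=80, tol=1e-8,
                             n_restarts=5)
        assert np.all(np.diff(ll) >= -1e-9)
        candidates = [est.A, est.A[::-1, ::-1]]  # label permutation
        err = min(np.abs(c - truth.A).max() for c in candidates)
        assert err < 0.05

    def test_monotone_from_generating_parameters(self, rng):
        truth = HmmParams([0.5, 0.5], [[0.9, 0.1], [0.2, 0.8]], np.eye(2) * 0.8 + 0.1)
        obs = rng.integers(0, 2, size=200)
        _, ll = baum_welch([obs], 2, 2, init=truth, max_iter=10)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_single_state_converges_to_empirical_frequencies(self):
        obs = np.array([0, 0, 1, 2, 2, 2, 1, 0, 2, 2])
        est, _ = baum_welch([obs], 1, 3, init=0, max_iter=2)
        freq = np.bincount(obs, minlength=3) / len(obs)
        np.testing.assert_allclose(est.B[0], freq, atol=1e-12)

    def test_multiple_sequences_accepted(self, rng):
        seqs = [rng.integers(0, 2, size=30) for _ in range(3)]
        est, ll = baum_welch(seqs, 2, 2, init=4, max_iter=15)
        assert np.all(np.diff(ll) >= -1e-9)
        np.testing.assert_allclose(est.A.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(est.B.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_sequence_list_rejected(self):
        with pytest.raises(ValueError):
            baum_welch([], 2, 2)


class TestSupervisedEstimators:
    def test_bigram_counting_by_hand(self):
        pi, a = estimate_supervised([[0, 0, 1, 1]], 2, pseudocount=0.0)
        np.testing.assert_allclose(a[0], [0.5, 0.5])
        np.testing.assert_allclose(a[1], [0.0, 1.0])
        np.testing.assert_allclose(pi, [1.0, 0.0])

    def test_smoothing_only_limit_is_uniform(self):
        pi, a = estimate_supervised([[]], 3, pseudocount=1.0)
        np.testing.assert_allclose(pi, 1 / 3)
        np.testing.assert_allclose(a, 1 / 3)

    def test_counts_invariant_to_sequence_order(self):
        s1, s2 = [0, 1, 1, 0], [1, 1, 0, 0, 2]
        r1 = estimate_supervised([s1, s2], 3, 1.0)
        r2 = estimate_supervised([s2, s1], 3, 1.0)
        np.testing.assert_allclose(r1[1], r2[1])

    def test_emission_identity_for_perfect_predictions(self):
        labels = np.array([0, 1, 2, 3] * 5)
        b = emission_from_confusion(labels, labels, 4, pseudocount=0.0)
        np.testing.assert_array_equal(b, np.eye(4))

    def test_emission_count_arithmetic(self):
        with pytest.warns(RuntimeWarning, match="absent"):
            b = emission_from_confusion([0, 0, 0, 0], [0, 0, 0, 1], 4, pseudocount=0.0)
        np.testing.assert_allclose(b[0], [0.75, 0.25, 0, 0])

    def test_emission_large_pseudocount_approaches_uniform(self):
        b = emission_from_confusion([0, 1] * 4, [0, 1] * 4, 2, pseudocount=1e9)
        np.testing.assert_allclose(b, 0.5, atol=1e-8)

    def test_absent_class_without_smoothing_warns_and_uniform_fills(self):
        with pytest.warns(RuntimeWarning, match="pseudocount is 0"):
            b = emission_from_confusion([0, 0], [0, 1], 3, pseudocount=0.0)
        np.testing.assert_allclose(b[1], 1 / 3)
        np.testing.assert_allclose(b[2], 1 / 3)
        np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-12)


class TestParamsValidationAndSerde:
    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            HmmParams([0.5, 0.5], [[0.9, 0.2], [0.5, 0.5]], np.eye(2))

    def test_round_trip(self, tmp_path, rng):
        params = random_params(4, 4, rng)
        path = tmp_path / "hmm.json"
        params.save(path)
        loaded = HmmParams.load(path)
        np.testing.assert_array_equal(params.A, loaded.A)
        np.testing.assert_array_equal(params.B, loaded.B)
        np.testing.assert_array_equal(params.pi, loaded.pi)

    def test_estimators_yield_stochastic_rows(self, rng):
        seqs = [rng.integers(0, 4, size=50) for _ in range(3)]
        pi, a = estimate_supervised(seqs, 4, 1.0)
        b = emission_from_confusion(seqs[0], seqs[1], 4, 1.0)
        assert abs(pi.sum() - 1) < 1e-12
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-12)
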