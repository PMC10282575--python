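"""Unit and property tests for the discrete Baum-Welch machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bwcrn.hmm import (
    HMMParams,
    ObservedSequence,
    OutOfDomainError,
    backward,
    brute_force_likelihood,
    bw_fit,
    check_theta_region,
    e_step,
    forward,
    log_likelihood,
    m_step,
    m_step_multi,
    sample_sequence,
)

from conftest import random_instance


class TestParamsAndSequences:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError):
            HMMParams([0.5, 0.5], [[0.9, 0.2], [0.5, 0.5]], [[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            HMMParams([0.7, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            HMMParams([1.0], [[1.0]], [[-0.2, 1.2]])

    def test_alphabet_order_is_declared_order(self):
        seq = ObservedSequence.from_tokens(["b", "a", "b"], ["a", "b"])
        assert seq.symbols.tolist() == [1, 0, 1]
        inferred = ObservedSequence.from_tokens(["b", "a", "b"])
        assert inferred.alphabet == ["b", "a"]

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="'c'"):
            ObservedSequence.from_tokens(["a", "c"], ["a", "b"])


class TestSampling:
    def test_deterministic_chain_emits_constant_sequence(self):
        params = HMMParams([1.0, 0.0], [[1, 0], [0, 1]], [[1, 0], [0, 1]])
        seq, hidden = sample_sequence(params, 20, seed=3)
        assert seq.symbols.tolist() == [0] * 20
        assert hidden.tolist() == [0] * 20

    def test_seed_reproducibility(self, toy3):
        s1, h1 = sample_sequence(toy3, 50, seed=11)
        s2, h2 = sample_sequence(toy3, 50, seed=11)
        assert s1.symbols.tolist() == s2.symbols.tolist()
        assert h1.tolist() == h2.tolist()

    def test_single_step_emission_frequencies_within_4_sigma(self):
        row = np.array([0.34, 0.33, 0.33])
        params = HMMParams([1.0, 0.0], [[1, 0], [0, 1]], np.vstack([row, row]))
        n = 10_000
        seq, _ = sample_sequence(params, n, seed=123)
        counts = seq.counts()
        for w in range(3):
            sigma = np.sqrt(n * row[w] * (1 - row[w]))
            assert abs(counts[w] - n * row[w]) < 4 * sigma


class TestLikelihoodOracle:
    def test_toy2_hand_enumeration(self, toy2, seq_ab):
        # 4 paths; only (H1,H2) survives the deterministic emissions
        assert brute_force_likelihood(toy2, seq_ab) == pytest.approx(0.25, abs=1e-15)

    def test_total_probability_over_all_sequences(self, toy3):
        import itertools

        total = sum(
            brute_force_likelihood(
                toy3, ObservedSequence(np.array(word), ["a", "b"])
            )
            for word in itertools.product(range(2), repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_hidden_state_degenerates_to_emission_product(self):
        params = HMMParams([1.0], [[1.0]], [[0.2, 0.3, 0.5]])
        seq = ObservedSequence(np.array([0, 2, 2, 1]), ["a", "b", "c"])
        assert brute_force_likelihood(params, seq) == pytest.approx(
            0.2 * 0.5 * 0.5 * 0.3, abs=1e-15
        )

    def test_enumeration_guard(self):
        params = HMMParams.uniform(3, 2)
        seq = ObservedSequence(np.zeros(20, dtype=int), ["a", "b"])
        with pytest.raises(ValueError, match="forward"):
            brute_force_likelihood(params, seq)


class TestForwardBackward:
    def test_toy3_hand_values(self, toy3, seq_ab):
        alpha, _ = forward(toy3, seq_ab, scaled=False)
        np.testing.assert_allclose(alpha[0], [0.375, 0.125], atol=1e-15)
        np.testing.assert_allclose(alpha[1], [0.0625, 0.1875], atol=1e-15)
        beta = backward(toy3, seq_ab, scaled=False)
        np.testing.assert_allclose(beta[1], [1.0, 1.0], atol=1e-15)
        np.testing.assert_allclose(beta[0], [0.5, 0.5], atol=1e-15)

    def test_zero_emission_column_propagates_zeros(self):
        params = HMMParams([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[1, 0], [1, 0]])
        seq = ObservedSequence(np.array([1, 0]), ["a", "b"])
        alpha, scale = forward(params, seq)
        assert np.all(alpha[0] == 0)
        assert scale[0] == 0
        assert log_likelihood(params, seq) == -np.inf

    @pytest.mark.parametrize("draw", range(12))
    def test_agreement_with_brute_force(self, draw):
        """Scaled forward and backward likelihoods equal explicit path
        enumeration to 1e-10 on small random instances."""
        rng = np.random.default_rng(1000 + draw)
        n_h = int(rng.integers(1, 4))
        L = int(rng.integers(2, 7))
        params = HMMParams.random(n_h, int(rng.integers(2, 4)), rng)
        seq, _ = sample_sequence(params, L, int(rng.integers(0, 2**31)))
        ref = brute_force_likelihood(params, seq)

        alpha_raw, _ = forward(params, seq, scaled=False)
        assert alpha_raw[-1].sum() == pytest.approx(ref, abs=1e-10)

        alpha, scale = forward(params, seq, scaled=True)
        assert np.exp(np.sum(np.log(scale))) == pytest.approx(ref, rel=1e-10)

        beta = backward(params, seq, scaled=False)
        lik_from_beta = float(
            np.sum(params.pi * params.psi[:, seq.symbols[0]] * beta[0])
        )
        assert lik_from_beta == pytest.approx(ref, abs=1e-10)
        assert log_likelihood(params, seq) == pytest.approx(np.log(ref), abs=1e-10)


class TestEStep:
    def test_toy3_hand_values(self, toy3, seq_ab):
        alpha, _ = forward(toy3, seq_ab)
        beta = backward(toy3, seq_ab)
        gamma, xi = e_step(toy3, seq_ab, alpha, beta)
        np.testing.assert_allclose(gamma, [[0.75, 0.25], [0.25, 0.75]], atol=1e-12)
        np.testing.assert_allclose(
            xi[0], [[0.1875, 0.5625], [0.0625, 0.1875]], atol=1e-12
        )

    def test_toy2_hand_values(self, toy2, seq_ab):
        alpha, _ = forward(toy2, seq_ab)
        beta = backward(toy2, seq_ab)
        gamma, xi = e_step(toy2, seq_ab, alpha, beta)
        np.testing.assert_allclose(gamma, [[1, 0], [0, 1]], atol=1e-12)
        np.testing.assert_allclose(xi[0], [[0, 1], [0, 0]], atol=1e-12)

    def test_scale_invariance(self, toy3, seq_ab, rng):
        alpha, _ = forward(toy3, seq_ab, scaled=False)
        beta = backward(toy3, seq_ab, scaled=False)
        g1, x1 = e_step(toy3, seq_ab, alpha, beta)
        c = rng.uniform(0.1, 10, size=(2, 1))
        d = rng.uniform(0.1, 10, size=(2, 1))
        g2, x2 = e_step(toy3, seq_ab, alpha * c, beta * d)
        np.testing.assert_allclose(g1, g2, atol=1e-12)
        np.testing.assert_allclose(x1, x2, atol=1e-12)

    @pytest.mark.parametrize("draw", range(8))
    def test_posterior_invariants(self, draw):
        """gamma rows sum to 1, xi slices sum to 1, and the xi marginal over
        destinations equals gamma at the source position."""
        rng = np.random.default_rng(2000 + draw)
        params, seq, _ = random_instance(rng)
        alpha, _ = forward(params, seq)
        beta = backward(params, seq)
        gamma, xi = e_step(params, seq, alpha, beta)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        np.testing.assert_allclose(xi.sum(axis=2), gamma[:-1], atol=1e-9)

    def test_zero_denominator_names_position(self):
        params = HMMParams([1.0, 0.0], [[1, 0], [0, 1]], [[1, 0], [1, 0]])
        seq = ObservedSequence(np.array([0, 1]), ["a", "b"])
        alpha, _ = forward(params, seq)
        beta = backward(params, seq)
        # beta vanishes at position 1 as well (the impossible suffix), so
        # the first offending position is reported
        with pytest.raises(OutOfDomainError, match="position 1"):
            e_step(params, seq, alpha, beta)


class TestMStep:
    def test_toy3_hand_ratios(self, toy3, seq_ab):
        alpha, _ = forward(toy3, seq_ab)
        beta = backward(toy3, seq_ab)
        gamma, xi = e_step(toy3, seq_ab, alpha, beta)
        theta_p, psi_p = m_step(gamma, xi, seq_ab)
        np.testing.assert_allclose(theta_p, [[0.25, 0.75], [0.25, 0.75]], atol=1e-12)
        np.testing.assert_allclose(psi_p, [[0.75, 0.25], [0.25, 0.75]], atol=1e-12)

    def test_single_position_direct_ratio(self):
        xi = np.array([[[0.2, 0.3], [0.1, 0.4]]])
        gamma = np.array([[0.5, 0.5], [0.5, 0.5]])
        seq = ObservedSequence(np.array([0, 1]), ["a", "b"])
        theta_p, _ = m_step(gamma, xi, seq)
        np.testing.assert_allclose(theta_p, [[0.4, 0.6], [0.2, 0.8]], atol=1e-12)

    def test_toy2_zero_row_raises(self, toy2, seq_ab):
        alpha, _ = forward(toy2, seq_ab)
        beta = backward(toy2, seq_ab)
        gamma, xi = e_step(toy2, seq_ab, alpha, beta)
        with pytest.raises(OutOfDomainError, match="row 2"):
            m_step(gamma, xi, seq_ab)

    @pytest.mark.parametrize("draw", range(6))
    def test_rows_sum_to_one(self, draw):
        rng = np.random.default_rng(3000 + draw)
        params, seq, _ = random_instance(rng)
        alpha, _ = forward(params, seq)
        beta = backward(params, seq)
        gamma, xi = e_step(params, seq, alpha, beta)
        theta_p, psi_p = m_step(gamma, xi, seq)
        np.testing.assert_allclose(theta_p.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(psi_p.sum(axis=1), 1.0, atol=1e-12)


class TestMStepMulti:
    def _posteriors(self, params, seq):
        alpha, _ = forward(params, seq)
        beta = backward(params, seq)
        return e_step(params, seq, alpha, beta)

    def test_single_sequence_reduction(self, toy3, seq_ab):
        gamma, xi = self._posteriors(toy3, seq_ab)
        t1, p1 = m_step(gamma, xi, seq_ab)
        t2, p2, pi2 = m_step_multi([gamma], [xi], [seq_ab], update_pi=False)
        np.testing.assert_allclose(t1, t2, atol=1e-15)
        np.testing.assert_allclose(p1, p2, atol=1e-15)
        assert pi2 is None

    def test_duplicated_sequence_leaves_update_unchanged(self, toy3, seq_ab):
        gamma, xi = self._posteriors(toy3, seq_ab)
        t1, p1, _ = m_step_multi([gamma], [xi], [seq_ab])
        t2, p2, _ = m_step_multi([gamma, gamma], [xi, xi], [seq_ab, seq_ab])
        np.testing.assert_allclose(t1, t2, atol=1e-15)
        np.testing.assert_allclose(p1, p2, atol=1e-15)

    def test_pi_update_averages_first_position_posteriors(self, seq_ab):
        gamma1 = np.array([[1.0, 0.0], [0.5, 0.5]])
        gamma2 = np.array([[0.0, 1.0], [0.5, 0.5]])
        xi = np.array([[[0.25, 0.25], [0.25, 0.25]]])
        _, _, pi_p = m_step_multi(
            [gamma1, gamma2], [xi, xi], [seq_ab, seq_ab], update_pi=True
        )
        np.testing.assert_allclose(pi_p, [0.5, 0.5], atol=1e-15)


class TestLogLikelihood:
    def test_toy2_value(self, toy2, seq_ab):
        assert log_likelihood(toy2, seq_ab) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_deterministic_chain_has_probability_one(self):
        params = HMMParams([1.0, 0.0], [[1, 0], [0, 1]], [[1, 0], [0, 1]])
        seq = ObservedSequence(np.zeros(10, dtype=int), ["a", "b"])
        assert log_likelihood(params, seq) == pytest.approx(0.0, abs=1e-12)

    def test_sums_over_sequences(self, toy3, seq_ab):
        single = log_likelihood(toy3, seq_ab)
        assert log_likelihood(toy3, [seq_ab, seq_ab]) == pytest.approx(
            2 * single, abs=1e-12
        )


class TestBaumWelchFit:
    def test_symmetric_fixed_point_from_uniform(self):
        tokens = ["v1"] * 49 + ["v2"] * 51
        seq = ObservedSequence.from_tokens(tokens, ["v1", "v2"])
        fit = bw_fit(HMMParams.uniform(2, 2), seq)
        np.testing.assert_allclose(fit.params.theta, 0.5, atol=1e-12)
        for row in fit.params.psi:
            np.testing.assert_allclose(sorted(row), [0.49, 0.51], atol=1e-12)

    def test_length5_boundary_equilibrium(self):
        from bwcrn.experiments import LENGTH5_SEQUENCE, default_length5_init

        seq = ObservedSequence.from_tokens(LENGTH5_SEQUENCE, ["v1", "v2"])
        fit = bw_fit(default_length5_init(), seq, max_iter=50_000)
        np.testing.assert_allclose(fit.params.theta, [[0, 1], [1, 0]], atol=1e-8)
        np.testing.assert_allclose(fit.params.psi, [[0, 1], [1, 0]], atol=1e-8)

    @pytest.mark.parametrize("draw", range(5))
    def test_loglik_monotone_and_improves_on_init(self, draw):
        rng = np.random.default_rng(4000 + draw)
        params, seq, _ = random_instance(rng)
        fit = bw_fit(params, seq, max_iter=200)
        hist = np.array(fit.loglik_history)
        assert np.all(np.diff(hist) >= -1e-8)
        assert hist[-1] >= hist[0] - 1e-12

    def test_positivity_preserved_from_positive_start(self, rng):
        """From strictly positive parameters and an alphabet-covering
        sequence, every iterate remains strictly positive."""
        params, seq, _ = random_instance(rng, n_hidden=2, n_symbols=2, L=8)
        fit = bw_fit(params, seq, max_iter=50, record_history=True)
        for p in fit.params_history:
            assert np.all(p.theta > 0)
            assert np.all(p.psi > 0)

    def test_rejects_too_short_sequences(self, toy3):
        seq = ObservedSequence(np.array([0]), ["a", "b"])
        with pytest.raises(ValueError, match="L >= 2"):
            bw_fit(toy3, seq)


class TestThetaRegion:
    def test_positive_params_inside(self, toy3, seq_ab):
        rep = check_theta_region(toy3, seq_ab)
        assert rep.in_theta
        assert rep.lemma_precondition

    def test_toy2_inside(self, toy2, seq_ab):
        assert check_theta_region(toy2, seq_ab).in_theta

    def test_cut_off_state_reported(self):
        # state 2 never entered (pi and incoming transitions zero) and its
        # emission row cannot produce the observed symbols
        params = HMMParams([1.0, 0.0], [[1, 0], [1, 0]], [[1, 0], [0, 1]])
        seq = ObservedSequence(np.array([0, 0]), ["a", "b"])
        rep = check_theta_region(params, seq)
        assert not rep.in_theta
        assert rep.offending_states == [1]


class TestHmmlearnCrossCheck:
    def test_update_matches_hmmlearn(self):
        """One Baum-Welch update agrees with hmmlearn's CategoricalHMM
        (independent implementation) from the same starting point."""
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(99)
        params, seq, _ = random_instance(rng, n_hidden=2, n_symbols=3, L=40)
        model = CategoricalHMM(
            n_components=2, init_params="", params="te", n_iter=1,
            implementation="scaling", tol=-np.inf,
        )
        model.startprob_ = params.pi.copy()
        model.transmat_ = params.theta.copy()
        model.emissionprob_ = params.psi.copy()
        model.fit(seq.symbols.reshape(-1, 1))

        fit = bw_fit(params, seq, max_iter=1, record_history=True)
        ours = fit.params_history[1]
        np.testing.assert_allclose(ours.theta, model.transmat_, atol=1e-8)
        np.testing.assert_allclose(ours.psi, model.emissionprob_, atol=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    L=st.integers(2, 6),
    n_h=st.integers(1, 3),
    n_v=st.integers(2, 3),
)
def test_forward_equals_enumeration_property(seed, L, n_h, n_v):
    """Property form of the likelihood oracle equivalence."""
    rng = np.random.default_rng(seed)
    params = HMMParams.random(n_h, n_v, rng)
    seq, _ = sample_sequence(params, L, seed + 1)
    ref = brute_force_likelihood(params, seq)
    alpha, _ = forward(params, seq, scaled=False)
    assert alpha[-1].sum() == pytest.approx(ref, abs=1e-10)
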