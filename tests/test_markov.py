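"""Markov chain estimation, model distance, permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegstates.markov import (
    MarkovChain,
    MarkovModel,
    estimate_markov,
    model_distance,
    permutation_test,
    sample_sequences,
    sequence_loglik,
)
from eegstates.simulate import TM_CONDITION_1, TM_CONDITION_2


def chain(tm):
    tm = np.asarray(tm, dtype=float)
    return MarkovModel(pi=np.full(tm.shape[0], 1 / tm.shape[0]), Tm=tm)


class TestEstimate:
    def test_hand_counted_example(self):
        M = estimate_markov(np.array([[1, 1, 2, 2], [1, 2, 2, 1]]), 2)
        np.testing.assert_allclose(M.pi, [1.0, 0.0])
        np.testing.assert_allclose(M.Tm, [[1 / 3, 2 / 3], [1 / 3, 2 / 3]])

    def test_deterministic_cycle_gives_permutation_matrix(self):
        S = np.tile([1, 2, 3], 5)[None, :]
        M = estimate_markov(S, 3)
        np.testing.assert_allclose(M.Tm, [[0, 1, 0], [0, 0, 1], [1, 0, 0]])

    def test_unvisited_state_gets_uniform_row(self):
        M = estimate_markov(np.array([[1, 2, 1, 2]]), 3)
        np.testing.assert_allclose(M.Tm[2], [1 / 3, 1 / 3, 1 / 3])
        assert M.pi[2] == 0.0

    def test_rows_stochastic(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 20, 25, rng)
        M = estimate_markov(S, 3)
        np.testing.assert_allclose(M.Tm.sum(axis=1), 1.0, atol=1e-12)
        assert M.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reference_chain_recovery(self, rng):
        for tm in (TM_CONDITION_1, TM_CONDITION_2):
            S = sample_sequences(chain(tm), 300, 25, rng)
            M = estimate_markov(S, 3)
            assert np.abs(M.Tm - tm).max() < 0.02

    def test_matches_baum_welch_with_identity_emissions(self, rng):
        from hmmlearn.hmm import CategoricalHMM

        true = MarkovModel(pi=np.array([0.3, 0.5, 0.2]),
                           Tm=np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3],
                                        [0.25, 0.25, 0.5]]))
        S = sample_sequences(true, 40, 20, rng)
        ours = estimate_markov(S, 3)
        hm = CategoricalHMM(n_components=3, init_params="", params="st",
                            n_iter=100, tol=1e-4, random_state=0)
        hm.startprob_ = np.full(3, 1 / 3)
        hm.transmat_ = np.full((3, 3), 1 / 3)
        hm.emissionprob_ = np.eye(3)
        hm.fit((S - 1).reshape(-1, 1), lengths=[S.shape[1]] * S.shape[0])
        np.testing.assert_allclose(hm.startprob_, ours.pi, atol=1e-6)
        np.testing.assert_allclose(hm.transmat_, ours.Tm, atol=1e-6)

    def test_short_sequences_raise(self):
        with pytest.raises(ValueError):
            estimate_markov(np.array([[1], [2]]), 2)


class TestLoglik:
    def test_own_deterministic_cycle_is_zero(self):
        S = np.tile([1, 2, 3], 4)[None, :]
        M = MarkovModel(pi=np.array([1.0, 0, 0]),
                        Tm=np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float))
        assert sequence_loglik(S, M) == pytest.approx(0.0)

    def test_uniform_closed_form(self):
        M = MarkovModel(pi=np.array([0.5, 0.5]), Tm=np.full((2, 2), 0.5))
        assert sequence_loglik(np.array([[1, 2, 1]]), M) == pytest.approx(3 * np.log(0.5))

    def test_zero_probability_is_floored_finite(self):
        M = MarkovModel(pi=np.array([1.0, 0.0]),
                        Tm=np.array([[1.0, 0.0], [0.5, 0.5]]))
        ll = sequence_loglik(np.array([[1, 2]]), M)
        assert np.isfinite(ll)
        assert ll == pytest.approx(np.log(2.2204e-16))

    def test_out_of_range_symbol_raises(self):
        M = MarkovModel(pi=np.array([0.5, 0.5]), Tm=np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            sequence_loglik(np.array([[1, 3]]), M)


class TestDistance:
    def test_identical_models_zero(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 10, 25, rng)
        M = estimate_markov(S, 3)
        assert model_distance(M, M, S, S) == 0.0

    def test_identical_sequences_zero(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 10, 25, rng)
        M1 = estimate_markov(S, 3)
        M2 = estimate_markov(S.copy(), 3)
        assert model_distance(M1, M2, S, S.copy()) == 0.0

    def test_reference_chains_strictly_negative(self, rng):
        S1 = sample_sequences(chain(TM_CONDITION_1), 300, 25, rng)
        S2 = sample_sequences(chain(TM_CONDITION_2), 300, 25, rng)
        d = model_distance(estimate_markov(S1, 3), estimate_markov(S2, 3), S1, S2)
        assert d < 0.0

    def test_q_mismatch_raises(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 4, 10, rng)
        M3 = estimate_markov(S, 3)
        M4 = estimate_markov(S, 4)
        with pytest.raises(ValueError):
            model_distance(M3, M4, S, S)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mle_pairs_never_positive(self, seed):
        r = np.random.default_rng(seed)
        Q = int(r.integers(2, 5))
        tm_a = r.dirichlet(np.ones(Q), size=Q)
        tm_b = r.dirichlet(np.ones(Q), size=Q)
        Sa = sample_sequences(chain(tm_a), 5, 10, r)
        Sb = sample_sequences(chain(tm_b), 5, 10, r)
        d = model_distance(estimate_markov(Sa, Q), estimate_markov(Sb, Q), Sa, Sb)
        assert d <= 1e-12


class TestPermutation:
    def test_detects_different_chains(self, rng):
        S1 = sample_sequences(chain(TM_CONDITION_1), 100, 25, rng)
        S2 = sample_sequences(chain(TM_CONDITION_2), 100, 25, rng)
        d_obs, null, p = permutation_test(S1, S2, 3, n_perm=200, seed=rng)
        assert p < 0.05
        assert d_obs <= null.min()

    def test_deterministic_given_seed(self, rng):
        S1 = sample_sequences(chain(TM_CONDITION_1), 10, 25, rng)
        S2 = sample_sequences(chain(TM_CONDITION_2), 10, 25, rng)
        a = permutation_test(S1, S2, 3, n_perm=50, seed=11)
        b = permutation_test(S1, S2, 3, n_perm=50, seed=11)
        assert a[0] == b[0] and a[2] == b[2]
        np.testing.assert_array_equal(a[1], b[1])

    def test_p_never_zero(self, rng):
        S1 = sample_sequences(chain(TM_CONDITION_1), 20, 25, rng)
        S2 = sample_sequences(chain(TM_CONDITION_2), 20, 25, rng)
        _, _, p = permutation_test(S1, S2, 3, n_perm=99, seed=0)
        assert p >= 1.0 / 100

    def test_invalid_n_perm_raises(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 4, 10, rng)
        with pytest.raises(ValueError):
            permutation_test(S, S, 3, n_perm=0)


class TestSampling:
    def test_absorbing_chain_constant_sequence(self, rng):
        M = MarkovModel(pi=np.array([0.0, 1.0, 0.0]), Tm=np.eye(3))
        S = sample_sequences(M, 3, 10, rng)
        assert (S == 2).all()

    def test_empirical_transition_frequencies(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 1, 100000, rng)[0]
        est = estimate_markov(S[None, :], 3)
        assert np.abs(est.Tm - TM_CONDITION_1).max() < 0.01

    def test_dwell_times_geometric(self, rng):
        M = chain(TM_CONDITION_1)
        S = sample_sequences(M, 1, 60000, rng)[0]
        # dwell episodes in state 1 follow Geometric(1 - Tm[0, 0])
        runs = []
        count = 0
        for s in S:
            if s == 1:
                count += 1
            elif count:
                runs.append(count)
                count = 0
        runs = np.array(runs)
        assert runs.size > 1e3
        q = 1 - TM_CONDITION_1[0, 0]
        kmax = 15
        obs = np.bincount(np.minimum(runs, kmax), minlength=kmax + 1)[1:]
        pmf = q * (1 - q) ** (np.arange(1, kmax + 1) - 1)
        pmf[-1] = (1 - q) ** (kmax - 1)  # tail bin
        exp = pmf * runs.size
        stat, p = stats.chisquare(obs, exp)
        assert p > 0.01


class TestEstimatorInterface:
    def test_fit_and_score(self, rng):
        S = sample_sequences(chain(TM_CONDITION_1), 20, 25, rng)
        mc = MarkovChain(n_states=3).fit(S)
        assert mc.transmat_.shape == (3, 3)
        assert mc.score(S) == pytest.approx(sequence_loglik(S, mc.model_()))
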