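"""Forward model: catch/discard predictions, likelihood, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm as norm_dist

from discardcast import (
    SelectivityOgive,
    discards_from_proportion,
    forward_series,
    log_likelihood,
    partition_discards,
    predicted_catch,
    predicted_discards,
    weighted_logQ,
)
from discardcast.ogives import ogive


def naive_forward(u, Q, capture, retention, pi, lengths, q):
    """Independent per-class summation of the catch and discard equations."""
    C = D = 0.0
    for i, length in enumerate(lengths):
        s = 1.0 / (1.0 + np.exp(-np.log(9) / capture.interval * (length - capture.l50)))
        r = 1.0 / (1.0 + np.exp(-np.log(9) / retention.interval * (length - retention.l50)))
        C += u * Q * s * pi[i]
        D += u * Q * (s * pi[i] + (q - 1.0) * r * s * pi[i])
    return C, D


class TestPredictedCatch:
    def test_single_class_hand_value(self):
        # s' = 0.5 at L50, pi = 1, u = 100, Q = 2 -> C = 100
        cap = SelectivityOgive(20, 6)
        assert predicted_catch(100, 2, cap, [1.0], [20.0]) == pytest.approx(100.0)

    def test_vanishing_selectivity_limit(self):
        cap = SelectivityOgive(1e6, 6)
        assert predicted_catch(100, 2, cap, [1.0], [20.0]) == pytest.approx(0.0, abs=1e-6)

    def test_linearity_in_q_ratio(self):
        cap = SelectivityOgive(22, 5)
        pi = np.array([0.3, 0.7])
        lengths = np.array([20.0, 30.0])
        assert predicted_catch(50, 4, cap, pi, lengths) == pytest.approx(
            2 * predicted_catch(50, 2, cap, pi, lengths))


class TestPredictedDiscards:
    def test_full_bulk_discarding_equals_catch(self):
        cap, ret = SelectivityOgive(20, 6), SelectivityOgive(25, 4)
        pi = np.array([0.4, 0.6])
        lengths = np.array([18.0, 28.0])
        c = predicted_catch(100, 2, cap, pi, lengths)
        d = predicted_discards(100, 2, cap, ret, pi, lengths, q_t=1.0)
        assert d == pytest.approx(c, rel=1e-12)

    def test_full_retention_no_bulk_gives_zero(self):
        cap, ret = SelectivityOgive(20, 6), SelectivityOgive(-1e5, 4)
        d = predicted_discards(100, 2, cap, ret, [0.5, 0.5], [18.0, 28.0], q_t=0.0)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_two_class_hand_value(self):
        # uQ = 100, s' = (1,1), pi = (.5,.5), r = (0,1), q = 0.2 -> D = 60
        lengths = np.array([10.0, 40.0])
        cap = SelectivityOgive(-1e4, 1e-2)   # s' ~ 1 everywhere
        ret = SelectivityOgive(25, 1e-2)     # r = knife edge at 25
        d = predicted_discards(100, 1, cap, ret, [0.5, 0.5], lengths, q_t=0.2)
        assert d == pytest.approx(60.0, rel=1e-9)


class TestForwardOracle:
    def test_matches_naive_on_random_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_classes = rng.integers(1, 6)
            lengths = np.sort(rng.uniform(5, 60, n_classes))
            pi = rng.dirichlet(np.ones(n_classes))
            cap = SelectivityOgive(rng.uniform(10, 40), rng.uniform(1, 10))
            ret = SelectivityOgive(rng.uniform(10, 40), rng.uniform(1, 10))
            u, q_ratio, q = rng.uniform(10, 1000), rng.uniform(0.1, 100), rng.uniform(0, 1)
            c_naive, d_naive = naive_forward(u, q_ratio, cap, ret, pi, lengths, q)
            c = predicted_catch(u, q_ratio, cap, pi, lengths)
            d = predicted_discards(u, q_ratio, cap, ret, pi, lengths, q)
            assert c == pytest.approx(c_naive, abs=1e-10 * max(1, abs(c_naive)))
            assert d == pytest.approx(d_naive, abs=1e-10 * max(1, abs(d_naive)))

    def test_sandwich_invariant_on_many_random_draws(self):
        # q * C <= D <= C over 1e4 random parameter draws
        rng = np.random.default_rng(11)
        n = 10_000
        lengths = np.arange(5.0, 61.0)
        for _ in range(10):
            pi = rng.dirichlet(np.ones(lengths.size))
            cap = SelectivityOgive(rng.uniform(8, 45), rng.uniform(0.5, 12))
            ret = SelectivityOgive(rng.uniform(8, 45), rng.uniform(0.5, 12))
            u = rng.uniform(1, 1000, n // 10)
            q_ratio = rng.uniform(0.01, 500, n // 10)
            q = rng.uniform(0, 1, n // 10)
            out = forward_series(u, q_ratio, cap, ret,
                                 np.tile(pi, (n // 10, 1)), lengths, q)
            assert np.all(out.discards <= out.catch * (1 + 1e-12))
            assert np.all(q * out.catch <= out.discards * (1 + 1e-12) + 1e-12)
            assert np.allclose(out.landings + out.discards, out.catch, rtol=1e-12)

    @given(q=st.floats(0, 1), rl50=st.floats(10, 40))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_discards_nondecreasing_in_q_and_rl50(self, q, rl50):
        lengths = np.arange(5.0, 61.0)
        pi = np.exp(-0.5 * ((lengths - 25) / 7) ** 2)
        pi /= pi.sum()
        cap = SelectivityOgive(15, 6)
        base = predicted_discards(100, 2, cap, SelectivityOgive(rl50, 6),
                                  pi, lengths, q)
        assert predicted_discards(100, 2, cap, SelectivityOgive(rl50, 6),
                                  pi, lengths, min(1.0, q + 0.1)) >= base - 1e-12
        assert predicted_discards(100, 2, cap, SelectivityOgive(rl50 * 1.1, 6),
                                  pi, lengths, q) >= base - 1e-12

    def test_homogeneity_in_u_times_q_ratio(self):
        lengths = np.arange(10.0, 31.0)
        pi = np.full(lengths.size, 1 / lengths.size)
        cap, ret = SelectivityOgive(15, 6), SelectivityOgive(22, 5)
        a = forward_series([100.0], [2.0], cap, ret, pi[None, :], lengths, [0.3])
        b = forward_series([200.0], [2.0], cap, ret, pi[None, :], lengths, [0.3])
        assert b.catch[0] == pytest.approx(2 * a.catch[0], rel=1e-12)
        assert b.discards[0] == pytest.approx(2 * a.discards[0], rel=1e-12)


class TestPartitionDiscards:
    def test_hand_value(self):
        quantity, size = partition_discards(100.0, 60.0, 0.2)
        assert quantity == pytest.approx(20.0)
        assert size == pytest.approx(40.0)

    def test_boundaries(self):
        q0, s0 = partition_discards(100.0, 60.0, 0.0)
        assert (q0, s0) == (0.0, 60.0)
        qb, sb = partition_discards(100.0, 20.0, 0.2)
        assert qb == pytest.approx(20.0)
        assert sb == pytest.approx(0.0)

    def test_precondition_violation(self):
        with pytest.raises(ValueError):
            partition_discards(100.0, 10.0, 0.5)  # D < q C


class TestLogLikelihood:
    def test_zero_residual_contribution(self):
        ll = log_likelihood([100.0], None, None, [100.0], None, None, 1.0, 1.0, 1.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_halving_sigma_adds_log_two_at_mode(self):
        ll1 = log_likelihood([50.0], None, None, [50.0], None, None, 1.0, 1.0, 1.0)
        ll2 = log_likelihood([50.0], None, None, [50.0], None, None, 0.5, 1.0, 1.0)
        assert ll2 - ll1 == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_naive_summation_on_toy_dataset(self):
        rng = np.random.default_rng(5)
        pred_u, pred_l, pred_d = rng.uniform(10, 100, 3), rng.uniform(10, 100, 3), rng.uniform(1, 50, 3)
        obs_u = pred_u * np.exp(rng.normal(0, 0.2, 3))
        obs_l = pred_l * np.exp(rng.normal(0, 0.1, 3))
        obs_d = pred_d * np.exp(rng.normal(0, 0.3, 3))
        obs_d[1] = np.nan  # missing datum is skipped
        sig = (0.2, 0.1, 0.3)
        expected = 0.0
        for obs, pred, s in [(obs_u, pred_u, sig[0]), (obs_l, pred_l, sig[1]),
                             (obs_d, pred_d, sig[2])]:
            for o, p in zip(obs, pred):
                if np.isfinite(o):
                    expected += norm_dist.logpdf(np.log(o), np.log(p), s)
        got = log_likelihood(obs_u, obs_l, obs_d, pred_u, pred_l, pred_d, *sig)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([-1.0], None, None, [1.0], None, None, 1, 1, 1)


class TestWeightedLogQ:
    def test_identity_weight(self):
        mat = np.log(np.array([[4.0, 8.0], [9.0, 2.0]]))
        out = weighted_logQ([1.0, 0.0], mat)
        assert np.allclose(out, mat[0])

    def test_geometric_mean(self):
        mat = np.log(np.array([[4.0], [9.0]]))
        out = weighted_logQ([0.5, 0.5], mat)
        assert np.exp(out[0]) == pytest.approx(6.0)

    def test_permutation_symmetry_with_equal_weights(self):
        mat = np.log(np.array([[4.0, 5.0], [9.0, 3.0], [2.0, 7.0]]))
        w = np.full(3, 1 / 3)
        assert np.allclose(weighted_logQ(w, mat), weighted_logQ(w, mat[::-1]))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_logQ([0.6, 0.6], np.zeros((2, 3)))


class TestDiscardsFromProportion:
    @pytest.mark.parametrize("L, p, expected", [(90, 0.1, 10), (100, 0.0, 0),
                                                (50, 0.5, 50)])
    def test_hand_cases(self, L, p, expected):
        assert discards_from_proportion(L, p) == pytest.approx(expected)

    def test_p_of_one_rejected(self):
        with pytest.raises(ValueError):
            discards_from_proportion(100, 1.0)
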