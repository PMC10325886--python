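"""Tests for embedding, simplex projection, sRMSE and the regularized S-map."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from divdyn.edm import (
    DEFAULT_PENALTY_GRID,
    EmbeddingError,
    delay_embed,
    estimate_theta,
    optimal_embedding,
    regularized_smap,
    simplex_cross_prediction,
    simplex_self_prediction,
    srmse,
)
from _oracles import ar1, embed_by_hand, logistic, self_prediction_oracle


class TestDelayEmbed:
    def test_direct_construction(self):
        points, times = delay_embed([1, 2, 3, 4], E=2, tau=1)
        np.testing.assert_array_equal(points, [[2, 1], [3, 2], [4, 3]])
        np.testing.assert_array_equal(times, [1, 2, 3])

    def test_identity_embedding(self):
        points, times = delay_embed([5.0, 6.0, 7.0], E=1)
        np.testing.assert_array_equal(points.ravel(), [5, 6, 7])

    def test_too_short_series(self):
        with pytest.raises(EmbeddingError, match="at least 4"):
            delay_embed([1, 2, 3], E=4, tau=1)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=5, max_size=40),
        st.integers(1, 4),
        st.integers(1, 2),
    )
    def test_matches_hand_embedding(self, x, E, tau):
        if len(x) < (E - 1) * tau + 1:
            return
        points, times = delay_embed(x, E, tau)
        hp, ht = embed_by_hand(x, E, tau)
        np.testing.assert_allclose(points, hp)
        np.testing.assert_array_equal(times, ht)
        assert len(points) == len(x) - (E - 1) * tau


class TestSrmse:
    def test_mean_prediction_is_exactly_one(self):
        obs = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert srmse(np.full(5, obs.mean()), obs) == 1.0

    def test_perfect_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert srmse(obs, obs) == 0.0

    def test_hand_arithmetic(self):
        assert srmse([1.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0, abs=1e-14)

    def test_constant_observations_undefined(self):
        assert math.isnan(srmse([1.0, 2.0], [3.0, 3.0]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-5, 5), st.floats(0.1, 10),
        st.lists(st.floats(-10, 10), min_size=3, max_size=20),
    )
    def test_affine_invariance(self, shift, scale, obs):
        obs = np.asarray(obs)
        if np.std(obs) < 1e-6:
            return
        pred = obs + np.linspace(-1, 1, obs.size)
        a = srmse(pred, obs)
        b = srmse(scale * pred + shift, scale * obs + shift)
        assert b == pytest.approx(a, rel=1e-9)


class TestSimplex:
    def test_constant_series_predicts_itself(self):
        res = simplex_self_prediction(np.full(20, 2.5), E=2)
        assert res.rmse == 0.0
        assert math.isnan(res.srmse)  # constant targets: baseline undefined

    def test_period_two_cycle_is_perfectly_predicted(self):
        x = np.array([0.2, 0.8] * 10)
        res = simplex_self_prediction(x, E=2)
        assert res.rmse == pytest.approx(0.0, abs=1e-14)
        assert res.srmse == pytest.approx(0.0, abs=1e-14)

    def test_logistic_window_matches_bruteforce_oracle(self):
        x = logistic(48, r=3.8, seed=2)
        res = simplex_self_prediction(x, E=2)
        preds, obs, rmse, s = self_prediction_oracle(x, E=2)
        np.testing.assert_allclose(res.predicted, preds, atol=1e-10)
        assert res.srmse == pytest.approx(s, abs=1e-10)

    def test_neighbor_shortage_raises(self):
        with pytest.raises((ValueError, EmbeddingError)):
            simplex_self_prediction([1.0, 2.0, 3.0, 4.0], E=3)

    def test_target_never_its_own_neighbor(self):
        # oracle exposes neighbor sets; cross-check structurally
        x = ar1(30, seed=3)
        _, sets = self_prediction_oracle(x, E=2)[0], None
        from _oracles import embed_by_hand, simplex_oracle

        points, times = embed_by_hand(x, 2)
        usable = [(p, t, x[t + 1]) for p, t in zip(points, times) if t + 1 < len(x)]
        pts, tms, futs = zip(*usable)
        _, neighbor_sets = simplex_oracle(pts, tms, futs, pts, tms, 2)
        for t, ns in zip(tms, neighbor_sets):
            assert t not in ns

    def test_cross_prediction_excludes_shared_points(self):
        # two fully overlapping windows reduce to leave-one-out
        x = ar1(40, seed=4)
        loo = simplex_self_prediction(x, E=2)
        cross = simplex_cross_prediction(x, x, E=2, lib_offset=0, tgt_offset=0)
        np.testing.assert_allclose(cross.predicted, loo.predicted, atol=1e-14)


class TestOptimalEmbedding:
    def test_singleton_grid(self):
        x = ar1(30, seed=0)
        E, errs = optimal_embedding(x, E_range=(3,))
        assert E == 3 and set(errs) == {3}

    def test_period_two_perfectly_predictable(self):
        x = np.array([0.1, 0.9] * 15)
        E, errs = optimal_embedding(x)
        assert errs[E] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_matches_bruteforce_argmin(self):
        x = np.random.default_rng(11).normal(size=40)
        E, errs = optimal_embedding(x, E_range=range(1, 6))
        oracle_errs = {e: self_prediction_oracle(x, e)[3] for e in range(1, 6)}
        assert E == min(oracle_errs, key=lambda e: (oracle_errs[e], e))
        for e in errs:
            assert errs[e] == pytest.approx(oracle_errs[e], abs=1e-10)

    def test_infeasible_range_raises(self):
        with pytest.raises(EmbeddingError):
            optimal_embedding(np.arange(6.0), E_range=(5, 6))


class TestRegularizedSmap:
    def test_linear_system_near_zero_error_at_theta_zero(self):
        # noiseless AR(1) decay: a global linear map fits exactly
        x = 2.0 * 0.8 ** np.arange(30)
        err = regularized_smap(x, E=1, theta=0.0)
        assert err < 0.05

    def test_theta_zero_equals_unweighted_penalized_oracle(self):
        x = ar1(36, seed=5)
        z = (x - x.mean()) / np.std(x)
        got = regularized_smap(x, E=2, theta=0.0)

        # independent oracle: plain unweighted elastic-net leave-one-out
        points, times = embed_by_hand(z, 2)
        usable = [(p, t, z[t + 1]) for p, t in zip(points, times) if t + 1 < len(z)]
        X = np.array([p for p, t, f in usable])
        y = np.array([f for p, t, f in usable])
        best = np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for lam in DEFAULT_PENALTY_GRID:
                errs = []
                for i in range(len(X)):
                    keep = np.arange(len(X)) != i
                    model = ElasticNet(alpha=lam, l1_ratio=0.5, max_iter=5000, tol=1e-8)
                    model.fit(X[keep], y[keep])
                    errs.append((model.predict(X[i : i + 1])[0] - y[i]) ** 2)
                best = min(best, float(np.mean(errs)))
        sd = np.sqrt(np.mean((y - y.mean()) ** 2))
        assert got == pytest.approx(np.sqrt(best) / sd, abs=1e-6)

    def test_scale_invariance(self):
        x = ar1(36, seed=6)
        a = regularized_smap(x, E=2, theta=1.0)
        b = regularized_smap(5.0 * x - 3.0, E=2, theta=1.0)
        assert b == pytest.approx(a, rel=1e-6)

    def test_constant_window_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regularized_smap(np.ones(20), E=1, theta=0.0)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            regularized_smap(ar1(20, seed=1), E=1, theta=-1.0)


class TestEstimateTheta:
    def test_singleton_grid_returns_zero(self):
        res = estimate_theta(ar1(30, seed=7), E=1, theta_grid=(0.0,))
        assert res.theta == 0.0

    def test_grid_without_zero_rejected(self):
        with pytest.raises(ValueError, match="include 0"):
            estimate_theta(ar1(30, seed=7), E=1, theta_grid=(0.5, 1.0))

    def test_chaotic_window_strongly_nonlinear(self):
        res = estimate_theta(logistic(48, seed=9), E=2)
        assert res.theta > 0
        # error improves markedly relative to the global linear map
        assert res.errors[res.grid > 0].min() < 0.5 * res.errors[0]

    def test_min_selection_is_argmin(self):
        res = estimate_theta(ar1(40, seed=8), E=1, selection="min")
        assert res.theta == res.grid[int(np.argmin([l.mean() for l in res.losses]))]
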