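"""Endpoint decomposition, expected margins, L1-hinge solver, fixed point."""

import itertools

import numpy as np
import pytest

from progpath import (
    MarginFeatureSelector,
    compute_endpoints,
    fit_feature_weights,
    select_features,
    solve_l1_hinge,
    tune_lambda_cv,
    weighted_block_distance,
)
from progpath.margin import (
    _project_l1_nonneg,
    expected_margin_vectors,
    hinge_objective,
    neighbor_probabilities,
)


class TestEndpoints:
    def test_midpoints_of_consecutive_times(self):
        np.testing.assert_allclose(compute_endpoints([1, 2, 3, 4]), [1.5, 2.5, 3.5])

    def test_ties_collapse(self):
        np.testing.assert_allclose(compute_endpoints([1, 1, 2]), [1.5])

    def test_constant_times_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            compute_endpoints([5, 5, 5])


class TestBlockDistance:
    def test_weighted_l1(self):
        assert weighted_block_distance([0, 0], [1, 2], [1, 1]) == 3.0
        assert weighted_block_distance([0, 0], [1, 2], [0, 1]) == 2.0
        assert weighted_block_distance([3, 4], [3, 4], [1, 1]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            weighted_block_distance([0], [1, 2], [1, 1])


class TestNeighborProbabilities:
    def _toy(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        return X, y

    def test_equidistant_candidates_split_evenly(self):
        X = np.array([[0.0], [-1.0], [1.0], [5.0]])
        y = np.array([4.0, 1.0, 1.5, 5.0])
        # sample 0 (y=4 > s=2): opposite side below s holds two candidates
        # at distance 1 each
        _, Q, _, _ = neighbor_probabilities(X, y, np.ones(1), 2.0, 0, kernel_width=1.0)
        np.testing.assert_allclose(Q, [0.5, 0.5])

    def test_single_candidate_probability_one(self):
        X, y = self._toy()
        opp_idx, Q, same_idx, P = neighbor_probabilities(
            X, y, np.ones(1), 1.5, 3, kernel_width=1.0
        )
        np.testing.assert_array_equal(opp_idx, [0])
        np.testing.assert_allclose(Q, [1.0])

    def test_infinite_width_uniform(self):
        X, y = self._toy()
        _, Q, _, P = neighbor_probabilities(X, y, np.ones(1), 2.5, 3, kernel_width=np.inf)
        np.testing.assert_allclose(Q, [0.5, 0.5])
        np.testing.assert_allclose(P, [1.0])

    def test_distributions_normalized_nonnegative(self, rng):
        X = rng.uniform(size=(20, 5))
        y = rng.uniform(1, 10, 20)
        w = rng.uniform(size=5)
        for s_k in compute_endpoints(y)[3:10]:
            for n in range(0, 20, 5):
                try:
                    _, Q, _, P = neighbor_probabilities(X, y, w, s_k, n, 2.0)
                except ValueError:
                    continue
                assert Q.sum() == pytest.approx(1.0, abs=1e-12)
                assert P.sum() == pytest.approx(1.0, abs=1e-12)
                assert (Q >= 0).all() and (P >= 0).all()


def _bruteforce_margin_vectors(X, y, w, endpoints, kernel_width):
    """Direct enumeration of the expected margin sums for every usable pair."""
    out = {}
    N = len(y)
    for n in range(N):
        for k, s in enumerate(endpoints):
            below = [j for j in range(N) if y[j] < s]
            above = [j for j in range(N) if y[j] > s]
            same = [j for j in (above if y[n] > s else below) if j != n]
            opp = below if y[n] > s else above
            if not same or not opp:
                continue
            d = lambda j: np.sum(w * np.abs(X[n] - X[j]))
            scale = np.mean([d(j) for j in range(N) if j != n])
            qw = np.array([np.exp(-(d(j)) / (scale * kernel_width)) for j in opp])
            pw = np.array([np.exp(-(d(j)) / (scale * kernel_width)) for j in same])
            qw, pw = qw / qw.sum(), pw / pw.sum()
            z = sum(q * np.abs(X[n] - X[j]) for q, j in zip(qw, opp)) - sum(
                p * np.abs(X[n] - X[j]) for p, j in zip(pw, same)
            )
            out[(n, k)] = z
    return out


class TestExpectedMargins:
    def test_narrow_kernel_recovers_hypothesis_margin(self):
        # kernel width -> 0: z = |x - nearmiss| - |x - nearhit|
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        mv = expected_margin_vectors(X, y, np.ones(1), np.array([2.5]), 1e-12)
        got = dict(zip(mv.pairs, mv.Z[:, 0]))
        # sample 0: nearmiss x2 (|0-10|=10), nearhit x1 (|0-1|=1) -> 9
        assert got[(0, 0)] == pytest.approx(9.0)
        assert got[(3, 0)] == pytest.approx(10.0 - 1.0)

    @pytest.mark.parametrize("kernel_width", [0.5, 2.0, 10.0])
    def test_matches_bruteforce_enumeration(self, rng, kernel_width):
        X = rng.uniform(size=(9, 3))
        y = rng.uniform(1, 5, 9)
        w = rng.uniform(0.1, 1, 3)
        endpoints = compute_endpoints(y)
        mv = expected_margin_vectors(X, y, w, endpoints, kernel_width)
        brute = _bruteforce_margin_vectors(X, y, w, endpoints, kernel_width)
        assert set(mv.pairs) == set(brute)
        for pair, z in zip(mv.pairs, mv.Z):
            np.testing.assert_allclose(z, brute[pair], atol=1e-10)

    def test_margin_vector_length_is_feature_count(self, rng):
        X = rng.uniform(size=(8, 6))
        y = rng.uniform(0, 3, 8)
        mv = expected_margin_vectors(X, y, np.ones(6), compute_endpoints(y), 2.0)
        assert mv.Z.shape[1] == 6


def _grid_oracle(z, lam, n=200):
    """Brute-force minimum of the single-vector hinge over the feasible square."""
    best = np.inf
    for w1 in np.linspace(0, lam, n):
        for w2 in np.linspace(0, lam, n):
            if w1 + w2 <= lam:
                best = min(best, max(0.0, 1.0 - (w1 * z[0] + w2 * z[1])))
    return best


class TestHingeSolver:
    @pytest.mark.parametrize(
        "z,lam,expected_obj",
        [((-1.0, -1.0), 1.0, 1.0), ((1.0, 0.0), 0.5, 0.5), ((2.0, 0.0), 1.0, 0.0)],
    )
    def test_single_vector_cases_match_grid_oracle(self, z, lam, expected_obj):
        Z = np.array([z])
        w, trace = solve_l1_hinge(Z, lam, max_iter=3000)
        oracle = _grid_oracle(np.asarray(z), lam)
        assert trace[-1] == pytest.approx(oracle, abs=1e-3)
        assert trace[-1] == pytest.approx(expected_obj, abs=1e-3)

    def test_incumbent_trace_non_increasing_and_feasible(self, rng):
        Z = rng.normal(size=(50, 8))
        lam = 2.0
        w, trace = solve_l1_hinge(Z, lam, max_iter=500)
        assert np.all(np.diff(trace) <= 0)
        assert (w >= 0).all()
        assert w.sum() <= lam + 1e-9

    def test_never_worse_than_init(self, rng):
        Z = rng.normal(size=(30, 5))
        w0 = rng.uniform(0, 0.2, 5)
        w, trace = solve_l1_hinge(Z, 1.0, w_init=w0, max_iter=200)
        assert trace[-1] <= hinge_objective(Z, _project_l1_nonneg(w0, 1.0)) + 1e-12

    def test_non_finite_margins_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            solve_l1_hinge(np.array([[np.nan, 1.0]]), 1.0)


class TestProjection:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadratic_program_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(scale=2, size=4)
        lam = rng.uniform(0.5, 3)
        w = _project_l1_nonneg(v, lam)
        assert (w >= 0).all() and w.sum() <= lam + 1e-12
        # no feasible grid point is closer to v
        grid = np.linspace(0, lam, 25)
        for cand in itertools.product(grid, repeat=4):
            c = np.array(cand)
            if c.sum() <= lam:
                assert np.sum((w - v) ** 2) <= np.sum((c - v) ** 2) + 1e-9


class TestFixedPoint:
    def _toy_cohort(self, rng, j_irrel=49):
        n = 60
        t = rng.uniform(0, 1, n)
        X = np.empty((n, 1 + j_irrel))
        X[:, 0] = t
        X[:, 1:] = rng.uniform(0, 1, (n, j_irrel))
        y = 1 + 10 * (1 - t) ** 2  # noiseless monotone in the relevant feature
        return X, y

    def test_relevant_feature_dominates(self, rng):
        X, y = self._toy_cohort(rng)
        fw = fit_feature_weights(X, y, lam=2.0, kernel_width=2.0, max_iter=30,
                                 solver_iter=400)
        assert fw.w[0] > 1e-3
        assert (fw.w[1:] < 1e-3).mean() >= 0.9

    def test_initialization_independence(self, rng):
        X, y = self._toy_cohort(rng, j_irrel=19)
        kw = dict(lam=2.0, kernel_width=2.0, max_iter=60, solver_iter=800, tol=1e-6)
        fw1 = fit_feature_weights(X, y, **kw)
        w0 = np.zeros(20)
        w0[3] = 2.0  # all budget on an irrelevant feature
        fw2 = fit_feature_weights(X, y, w_init=w0, **kw)
        assert np.abs(fw1.w - fw2.w).max() < 1e-3

    def test_tiny_lambda_shrinks_weights_to_zero(self, rng):
        X, y = self._toy_cohort(rng, j_irrel=9)
        fw = fit_feature_weights(X, y, lam=1e-6, kernel_width=2.0, max_iter=5)
        assert fw.w.sum() <= 1e-6 + 1e-12

    def test_feature_permutation_equivariance(self, rng):
        X, y = self._toy_cohort(rng, j_irrel=9)
        fw = fit_feature_weights(X, y, lam=2.0, kernel_width=2.0, max_iter=20,
                                 solver_iter=400)
        perm = rng.permutation(10)
        fw_p = fit_feature_weights(X[:, perm], y, lam=2.0, kernel_width=2.0,
                                   max_iter=20, solver_iter=400)
        np.testing.assert_allclose(fw_p.w, fw.w[perm], atol=1e-10)


class TestSelectFeatures:
    def test_threshold_rule(self):
        w = np.array([0.5, 1e-4, 0.002])
        np.testing.assert_array_equal(select_features(w, 1e-3), [0, 2])

    def test_all_below_threshold_warns(self):
        with pytest.warns(UserWarning, match="threshold"):
            idx = select_features(np.full(4, 1e-5), 1e-3)
        assert idx.size == 0

    def test_zero_threshold_keeps_positive(self):
        w = np.array([0.0, 0.1, 1e-8])
        np.testing.assert_array_equal(select_features(w, 0.0), [1, 2])


class TestLambdaCV:
    def test_single_value_grid_returned(self, rng):
        t = rng.uniform(0, 1, 30)
        X = np.column_stack([t, rng.uniform(0, 1, 30)])
        y = 1 + 5 * (1 - t)
        lam, scores = tune_lambda_cv(X, y, [0.7], folds=3, seed=0, max_iter=10)
        assert lam == 0.7 and set(scores) == {0.7}

    def test_structured_toy_keeps_relevant_feature(self, rng):
        n = 50
        t = rng.uniform(0, 1, n)
        X = np.empty((n, 10))
        X[:, 0] = t
        X[:, 1:] = rng.uniform(0, 1, (n, 9))
        y = 1 + 10 * (1 - t) ** 2
        lam, _ = tune_lambda_cv(X, y, [0.5, 2.0], folds=3, seed=1, max_iter=15,
                                solver_iter=300)
        fw = fit_feature_weights(X, y, lam, kernel_width=2.0, max_iter=15,
                                 solver_iter=300)
        assert 0 in set(select_features(fw).tolist())

    def test_pure_noise_prefers_smallest_lambda(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.uniform(size=(24, 6))
            y = r.uniform(1, 5, 24)
            lam, _ = tune_lambda_cv(X, y, [0.2, 5.0], folds=3, seed=seed,
                                    max_iter=8, solver_iter=200)
            hits += lam == 0.2
        assert hits >= 8


class TestEstimatorApi:
    def test_fit_transform_selects_columns(self, rng):
        n = 40
        t = rng.uniform(0, 1, n)
        X = np.column_stack([t, rng.uniform(0, 1, (n, 7)).T.reshape(7, n).T])
        y = 1 + 8 * (1 - t) ** 2
        sel = MarginFeatureSelector(lam=2.0, max_iter=15, solver_iter=300).fit(X, y)
        assert sel.weights_.shape == (8,)
        Xt = sel.transform(X)
        assert Xt.shape[1] == sel.get_support().sum() >= 1

    def test_get_set_params_roundtrip(self):
        sel = MarginFeatureSelector(lam=3.0, kernel_width=7.0)
        params = sel.get_params()
        assert params["lam"] == 3.0
        sel2 = MarginFeatureSelector().set_params(**params)
        assert sel2.kernel_width == 7.0
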