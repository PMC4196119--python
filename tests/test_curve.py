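"""Principal-curve EM, geometry queries, and elbow model selection."""

import numpy as np
import pytest
import scipy.special

from progpath import (
    CurveTopology,
    ElbowSweep,
    PrincipalCurve,
    PrincipalCurveModel,
    curve_length,
    elbow_select,
    em_fit,
    fitting_error,
    init_topology,
    log_likelihood,
    project_samples,
    simulate_elbow,
    sweep_sigma,
)
from progpath.curve import default_sigma_grid


def _gmm_em_oracle(X, mu0, p0, sigma, n_iter):
    """Textbook isotropic fixed-variance Gaussian-mixture EM."""
    mu, p = mu0.copy(), p0.copy()
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - mu[None]) ** 2).sum(axis=2)
        logw = np.log(p)[None, :] - d2 / (2 * sigma**2)
        logr = logw - scipy.special.logsumexp(logw, axis=1, keepdims=True)
        r = np.exp(logr)
        tot = r.sum(axis=0)
        mu = (r.T @ X) / tot[:, None]
        p = tot / tot.sum()
    return mu, p


class TestInitTopology:
    def test_pc1_collinear_equally_spaced(self):
        X = np.linspace(0, 9, 10)[:, None] * np.array([[1.0, 2.0]])
        topo, nodes = init_topology(X, "pc1", n_nodes=5)
        assert topo.edges == [(0, 1), (1, 2), (2, 3), (3, 4)]
        gaps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        np.testing.assert_allclose(gaps, gaps[0])

    def test_collinear_centroids_make_path(self):
        cents = np.array([[0.0, 0], [1, 0], [2, 0]])
        topo, nodes = init_topology(np.zeros((4, 2)), "centroids", centroids=cents, n_nodes=9)
        g = topo.graph()
        assert max(dict(g.degree()).values()) == 2  # no branch

    def test_y_centroids_make_degree3_node(self):
        cents = np.array([[0.0, 0], [1, 0], [2, 1], [2, -1]])
        topo, _ = init_topology(np.zeros((4, 2)), "centroids", centroids=cents, n_nodes=12)
        degs = dict(topo.graph().degree()).values()
        assert max(degs) == 3 and sum(d == 1 for d in degs) == 3

    def test_too_few_centroids_rejected(self):
        with pytest.raises(ValueError, match="centroid"):
            init_topology(np.zeros((4, 2)), "centroids", centroids=np.zeros((1, 2)))


class TestEmFit:
    def test_single_node_converges_to_data_mean(self, rng):
        X = rng.normal(size=(30, 3))
        topo = CurveTopology(1, [])
        model = em_fit(X, topo, X[:1].copy(), sigma=1.0, max_iter=2)
        np.testing.assert_allclose(model.mu[0], X.mean(axis=0), atol=1e-12)

    def test_matches_gmm_em_oracle_without_reparameterization(self, rng):
        X = rng.normal(size=(40, 3))
        topo, nodes = init_topology(X, "pc1", n_nodes=5)
        model = em_fit(X, topo, nodes, sigma=1.0, reparameterize=False, tol=0, max_iter=10)
        mu_o, p_o = _gmm_em_oracle(X, nodes, np.full(5, 0.2), 1.0, 10)
        np.testing.assert_allclose(model.mu, mu_o, atol=1e-10)
        np.testing.assert_allclose(model.p, p_o, atol=1e-10)

    def test_loglik_monotone_without_reparameterization(self, rng):
        X = rng.normal(size=(60, 4))
        topo, nodes = init_topology(X, "pc1", n_nodes=8)
        model = em_fit(X, topo, nodes, sigma=0.8, reparameterize=False, tol=0, max_iter=30)
        assert np.all(np.diff(model.loglik_trace) >= -1e-8)

    def test_equidistant_sample_splits_responsibility(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 5.0]])
        topo = CurveTopology(2, [(0, 1)])
        model = em_fit(X[2:3], topo, X[:2].copy(), sigma=1.0, max_iter=1,
                       reparameterize=False)
        # symmetric sample pulls both nodes identically: they stay symmetric
        assert abs(model.mu[0][0] - (2.0 - model.mu[1][0])) < 1e-12

    def test_mixing_weights_sum_to_one(self, bifurcation_small):
        X = bifurcation_small[0].values
        topo, nodes = init_topology(X, "pc1", n_nodes=20)
        model = em_fit(X, topo, nodes, sigma=0.3, max_iter=30)
        assert model.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (model.p >= 0).all()


class TestLogLikelihood:
    def test_closed_form_single_node(self):
        # one node at the mean of {-1, +1}, sigma 1: average log density is
        # -(log(2 pi) + 1)/2 per point
        X = np.array([[-1.0], [1.0]])
        topo = CurveTopology(1, [])
        model = PrincipalCurveModel(np.array([[0.0]]), np.array([1.0]), 1.0, topo)
        expected = 2 * (-0.5 * np.log(2 * np.pi) - 0.5)
        assert log_likelihood(X, model) == pytest.approx(expected, abs=1e-12)

    def test_duplicating_samples_doubles_loglik(self, rng):
        X = rng.normal(size=(15, 2))
        topo, nodes = init_topology(X, "pc1", n_nodes=4)
        model = em_fit(X, topo, nodes, sigma=0.7, max_iter=5)
        ll = log_likelihood(X, model)
        assert log_likelihood(np.vstack([X, X]), model) == pytest.approx(2 * ll)


class TestGeometry:
    def test_curve_length_additive(self):
        topo = CurveTopology(3, [(0, 1), (1, 2)])
        model = PrincipalCurveModel(
            np.array([[0.0, 0], [3, 0], [3, 4]]), np.full(3, 1 / 3), 1.0, topo
        )
        assert curve_length(model) == pytest.approx(7.0)

    def test_samples_on_polyline_have_zero_error(self):
        topo = CurveTopology(3, [(0, 1), (1, 2)])
        model = PrincipalCurveModel(
            np.array([[0.0, 0], [1, 0], [1, 1]]), np.full(3, 1 / 3), 1.0, topo
        )
        X = np.array([[0.5, 0.0], [1.0, 0.5], [1.0, 1.0]])
        assert fitting_error(X, model) == pytest.approx(0.0, abs=1e-24)

    def test_single_node_error_is_total_ss(self, rng):
        X = rng.normal(size=(20, 3))
        topo = CurveTopology(1, [])
        mu = X.mean(axis=0, keepdims=True)
        model = PrincipalCurveModel(mu, np.array([1.0]), 1.0, topo)
        assert fitting_error(X, model) == pytest.approx(((X - mu) ** 2).sum())

    def test_error_matches_dense_sampling_oracle(self, rng):
        X = rng.normal(size=(25, 3))
        topo, nodes = init_topology(X, "pc1", n_nodes=6)
        model = em_fit(X, topo, nodes, sigma=0.5, max_iter=10)
        dense = 0.0
        ts = np.linspace(0, 1, 10001)
        for x in X:
            best = np.inf
            for a, b in topo.edges:
                pts = model.mu[a] + ts[:, None] * (model.mu[b] - model.mu[a])
                best = min(best, ((pts - x) ** 2).sum(axis=1).min())
            dense += best
        assert fitting_error(X, model) == pytest.approx(dense, rel=1e-6)

    def test_projection_beats_every_node(self, rng):
        X = rng.normal(size=(30, 2)) * 2
        topo, nodes = init_topology(X, "pc1", n_nodes=7)
        model = em_fit(X, topo, nodes, sigma=0.5, max_iter=10)
        proj = project_samples(X, model)
        node_d = np.linalg.norm(X[:, None, :] - model.mu[None], axis=2).min(axis=1)
        assert np.all(proj["distance"] <= node_d + 1e-12)

    def test_projection_arc_length_semantics(self):
        topo = CurveTopology(3, [(0, 1), (1, 2)])
        model = PrincipalCurveModel(
            np.array([[0.0, 0], [2, 0], [2, 2]]), np.full(3, 1 / 3), 1.0, topo, root=0
        )
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0], [2.0, 2.0]])
        proj = project_samples(X, model)
        # node hit -> node arc length; perpendicular foot -> foot arc length
        np.testing.assert_allclose(proj["arc_length"], [0.0, 1.0, 3.0, 4.0])


class TestSweepAndElbow:
    def test_exact_two_line_recovery(self):
        lengths, errors = simulate_elbow(l_star=20.0, noise_sd=0.0)
        sweep = ElbowSweep(np.arange(len(lengths), dtype=float), lengths, errors)
        elbow_select(sweep)
        assert sweep.breakpoint_length == pytest.approx(20.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_recovery_within_ten_percent(self, seed):
        lengths, errors = simulate_elbow(l_star=20.0, noise_sd=0.01, seed=seed)
        sweep = ElbowSweep(np.arange(len(lengths), dtype=float), lengths, errors)
        elbow_select(sweep)
        assert abs(sweep.breakpoint_length - 20.0) / 20.0 < 0.10

    def test_collinear_warns_and_picks_smallest_length(self):
        x = np.linspace(1, 10, 8)
        sweep = ElbowSweep(np.arange(8.0), x, 100 - 3 * x)
        with pytest.warns(UserWarning, match="elbow"):
            s = elbow_select(sweep)
        assert s == sweep.sigmas[np.argmin(sweep.lengths)]

    def test_error_monotone_in_length_on_bifurcation(self, bifurcation_small):
        X = bifurcation_small[0].values
        topo, nodes = init_topology(X, "pc1", n_nodes=30)
        grid = default_sigma_grid(X, n=8)
        sweep, _ = sweep_sigma(X, topo, nodes, grid, max_iter=60)
        order = np.argsort(sweep.lengths)
        err = sweep.errors[order]
        assert np.all(np.diff(err) <= 0.01 * err[:-1] + 1e-12)

    def test_warm_start_close_to_cold_start(self, rng):
        # near-linear cloud: the likelihood surface is effectively unimodal,
        # so warm- and cold-started EM must land on the same optimum
        t = rng.uniform(0, 4, 120)
        X = np.column_stack([t, 0.5 * t]) + rng.normal(0, 0.05, (120, 2))
        topo, nodes = init_topology(X, "pc1", n_nodes=8)
        rms = np.sqrt(((X - X.mean(0)) ** 2).sum(1).mean())
        grid = np.geomspace(0.4 * rms, 0.1 * rms, 4)  # above the multimodal regime
        _, models = sweep_sigma(X, topo, nodes, grid, max_iter=300)
        cold = em_fit(X, topo, nodes, grid[-1], max_iter=300)
        ll_warm = models[-1].loglik_trace[-1]
        ll_cold = cold.loglik_trace[-1]
        assert abs(ll_warm - ll_cold) / abs(ll_cold) < 1e-3

    def test_sweep_requires_descending_grid(self, rng):
        X = rng.normal(size=(30, 2))
        topo, nodes = init_topology(X, "pc1", n_nodes=5)
        with pytest.raises(ValueError, match="descending"):
            sweep_sigma(X, topo, nodes, np.array([0.1, 1.0]))


class TestEstimator:
    def test_fit_transform_roundtrip(self, bifurcation_small):
        X = bifurcation_small[0].values[:200]
        pc = PrincipalCurve(n_nodes=20, sigma=0.3, max_iter=40).fit(X)
        coords = pc.transform(X)
        assert coords.shape == (200, 1)
        assert (coords >= 0).all()

    def test_json_roundtrip(self, bifurcation_small):
        X = bifurcation_small[0].values[:100]
        pc = PrincipalCurve(n_nodes=10, sigma=0.4, max_iter=20).fit(X)
        back = PrincipalCurveModel.from_json(pc.model_.to_json())
        np.testing.assert_allclose(back.mu, pc.model_.mu)
        assert back.topology.edges == pc.model_.topology.edges


class TestRestartStability:
    def test_deterministic_fit_close_to_best_restart(self, bifurcation_small):
        """The deterministic initialization lands within 5% fitting error of
        the best of 3 jittered restarts."""
        X = bifurcation_small[0].values[:250]
        base = PrincipalCurve(n_nodes=20, sigma=0.3, max_iter=60).fit(X)
        jit = PrincipalCurve(n_nodes=20, sigma=0.3, max_iter=60,
                             n_restarts=3, random_state=0).fit(X)
        e0 = fitting_error(X, base.model_)
        e1 = fitting_error(X, jit.model_)
        assert e0 <= 1.05 * e1 + 1e-12

    def test_error_trends_down_with_more_nodes(self, bifurcation_small):
        """More nodes give a strictly better fit over a wide gap; adjacent
        node counts may swap within a few percent because EM maximizes
        likelihood, not fitting error."""
        X = bifurcation_small[0].values[:250]
        errs = []
        for m in (5, 10, 20):
            pc = PrincipalCurve(n_nodes=m, sigma=0.3, max_iter=60).fit(X)
            errs.append(fitting_error(X, pc.model_))
        assert errs[2] < errs[0]
        assert errs[1] <= 1.10 * errs[0] and errs[2] <= 1.10 * errs[1]
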