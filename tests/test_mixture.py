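import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from gazeclass.mixture import (
    ClusterAssignment,
    GaussianComponent,
    InsufficientDataError,
    MixtureModel,
    NumericalError,
    assign_clusters,
    bic,
    cluster_ellipses,
    component_density,
    e_step,
    fit_em,
    m_step,
    select_k,
)


def make_model(weights, means, covs):
    comps = [GaussianComponent(w, np.array(m, float), np.array(c, float))
             for w, m, c in zip(weights, means, covs)]
    return MixtureModel(comps, log_likelihood=0.0, n_observations=0)


I2 = np.eye(2)


class TestComponentDensity:
    def test_at_mode_identity_cov(self):
        c = GaussianComponent(1.0, [3.0, 4.0], I2)
        assert component_density([3.0, 4.0], c) == pytest.approx(0.15915494309, abs=1e-9)

    def test_unit_distance_identity_cov(self):
        c = GaussianComponent(1.0, [0.0, 0.0], I2)
        assert component_density([1.0, 0.0], c) == pytest.approx(0.09653235263, abs=1e-9)

    def test_integrates_to_one(self, rng):
        a = rng.uniform(0.5, 2.0, size=(2, 2))
        cov = a @ a.T + 0.5 * I2
        c = GaussianComponent(1.0, [0.3, -0.7], cov)
        # quadrature oracle over a wide grid
        lim = 10 * np.sqrt(np.max(np.linalg.eigvalsh(cov)))
        xs = np.linspace(-lim, lim, 400)
        h = xs[1] - xs[0]
        gx, gy = np.meshgrid(xs + 0.3, xs - 0.7)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        dens = multivariate_normal.pdf(pts, mean=[0.3, -0.7], cov=cov)
        mine = np.array([component_density(p, c) for p in pts[::997]])
        assert np.allclose(mine, dens[::997], rtol=1e-10)
        assert dens.sum() * h * h == pytest.approx(1.0, abs=1e-3)

    def test_singular_cov_raises(self):
        c = GaussianComponent(1.0, [0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(NumericalError):
            component_density([0.0, 0.0], c)


class TestEStep:
    def test_single_component_all_ones(self, rng):
        model = make_model([1.0], [[0, 0]], [I2])
        pts = rng.normal(size=(7, 2))
        a = e_step(pts, model)
        assert np.allclose(a.responsibilities, 1.0)
        assert np.allclose(a.responsibilities.sum(axis=1), 1.0)

    def test_identical_components_half_half(self, rng):
        model = make_model([0.5, 0.5], [[1, 2], [1, 2]], [I2, I2])
        a = e_step(rng.normal(size=(9, 2)), model)
        assert np.allclose(a.responsibilities, 0.5)

    def test_matches_direct_formula(self, rng):
        """Direct evaluation of the responsibility formula with scipy densities."""
        means = rng.normal(scale=3, size=(3, 2))
        covs = []
        for _ in range(3):
            a = rng.normal(size=(2, 2))
            covs.append(a @ a.T + 0.5 * I2)
        w = rng.dirichlet(np.ones(3))
        model = make_model(w, means, covs)
        pts = rng.normal(scale=3, size=(5, 2))
        a = e_step(pts, model)
        for i in range(5):
            dens = np.array(
                [w[j] * multivariate_normal.pdf(pts[i], means[j], covs[j])
                 for j in range(3)]
            )
            assert np.allclose(a.responsibilities[i], dens / dens.sum(), atol=1e-10)
        assert np.allclose(a.cluster_mass, a.responsibilities.sum(axis=0))

    def test_rows_sum_to_one(self, rng):
        model = make_model([0.2, 0.8], [[0, 0], [5, 5]], [I2, 2 * I2])
        a = e_step(rng.normal(scale=4, size=(50, 2)), model)
        assert np.allclose(a.responsibilities.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def test_one_hot_reduces_to_subset_moments(self, rng):
        pts = rng.normal(size=(10, 2))
        resp = np.zeros((10, 2))
        resp[:6, 0] = 1.0
        resp[6:, 1] = 1.0
        model = m_step(pts, resp)
        assert np.allclose(model.means[0], pts[:6].mean(axis=0), atol=1e-12)
        assert np.allclose(model.covariances[1], np.cov(pts[6:].T, bias=True), atol=1e-10)
        assert np.allclose(model.weights, [0.6, 0.4])

    def test_uniform_resp_gives_grand_mean(self, rng):
        pts = rng.normal(size=(8, 2))
        model = m_step(pts, np.full((8, 2), 0.5))
        assert np.allclose(model.means[0], pts.mean(axis=0))
        assert np.allclose(model.means[1], pts.mean(axis=0))

    def test_matches_brute_force(self, rng):
        """Brute-force weighted-moment oracle on N = 6."""
        pts = rng.normal(scale=2, size=(6, 2))
        raw = rng.uniform(0.1, 1.0, size=(6, 3))
        resp = raw / raw.sum(axis=1, keepdims=True)
        model = m_step(pts, resp)
        n = 6
        for j in range(3):
            pi = sum(resp[i, j] for i in range(n)) / n
            mu = sum(resp[i, j] * pts[i] for i in range(n)) / sum(resp[:, j])
            cov = sum(
                resp[i, j] * np.outer(pts[i] - mu, pts[i] - mu) for i in range(n)
            ) / sum(resp[:, j])
            assert model.weights[j] == pytest.approx(pi, abs=1e-10)
            assert np.allclose(model.means[j], mu, atol=1e-10)
            assert np.allclose(model.covariances[j], cov, atol=1e-10)

    def test_degenerate_cluster_raises(self, rng):
        pts = rng.normal(size=(5, 2))
        resp = np.column_stack([np.ones(5), np.zeros(5)])
        from gazeclass.mixture import DegenerateClusterError

        with pytest.raises(DegenerateClusterError):
            m_step(pts, resp)


class TestFitEm:
    def test_k1_closed_form(self, rng):
        pts = rng.normal(scale=3, size=(100, 2))
        model = fit_em(pts, 1, seed=0, n_restarts=1)
        assert np.allclose(model.means[0], pts.mean(axis=0), atol=1e-8)
        assert np.allclose(model.covariances[0], np.cov(pts.T, bias=True), atol=1e-6)
        assert model.weights[0] == 1.0

    def test_two_blob_recovery(self, two_blob_points):
        model = fit_em(two_blob_points, 2, seed=0)
        order = np.argsort(model.means[:, 0])
        assert np.allclose(model.means[order], [[0, 0], [10, 0]], atol=0.5)
        assert np.allclose(model.weights, 0.5, atol=0.05)
        assert model.converged

    def test_restarts_dominate_single(self, two_blob_points):
        multi = fit_em(two_blob_points, 2, seed=7, n_restarts=8)
        single = fit_em(two_blob_points, 2, seed=7, n_restarts=1)
        assert multi.log_likelihood >= single.log_likelihood - 1e-9

    def test_insufficient_data(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_em(rng.normal(size=(3, 2)), 5)

    def test_ll_monotone(self, two_blob_points):
        model = fit_em(two_blob_points, 3, seed=1, n_restarts=1)
        assert np.all(np.diff(model.ll_trace) >= -1e-8)

    def test_em_fixed_point(self, two_blob_points):
        model = fit_em(two_blob_points, 2, seed=0, tol=1e-10, max_iter=2000)
        refit = m_step(two_blob_points, e_step(two_blob_points, model))
        assert np.allclose(refit.means, model.means, atol=1e-4)
        assert np.allclose(refit.weights, model.weights, atol=1e-6)

    def test_translation_invariance(self, two_blob_points):
        shift = np.array([123.0, -456.0])
        m0 = fit_em(two_blob_points, 2, seed=3, n_restarts=2)
        m1 = fit_em(two_blob_points + shift, 2, seed=3, n_restarts=2)
        assert np.allclose(m1.means, m0.means + shift, atol=1e-6)
        assert np.allclose(m1.covariances, m0.covariances, atol=1e-6)
        assert np.allclose(m1.weights, m0.weights, atol=1e-9)
        assert m1.log_likelihood == pytest.approx(m0.log_likelihood, abs=1e-6)


class TestBic:
    def test_direct_formula(self):
        model = make_model([1.0], [[0, 0]], [I2])
        model.log_likelihood = -100.0
        model.n_observations = 100
        assert bic(model) == pytest.approx(223.02585093, abs=1e-6)

    def test_doubling_n_adds_m_ln2(self):
        model = make_model([0.5, 0.5], [[0, 0], [1, 1]], [I2, I2])
        model.log_likelihood = -50.0
        model.n_observations = 64
        b1 = bic(model)
        model.n_observations = 128
        assert bic(model) - b1 == pytest.approx(11 * np.log(2), abs=1e-10)

    def test_n_zero_raises(self):
        model = make_model([1.0], [[0, 0]], [I2])
        with pytest.raises(ValueError):
            bic(model)


class TestSelectK:
    def test_single_blob_selects_one(self, rng):
        pts = rng.normal(scale=2, size=(300, 2))
        model, trace = select_k(pts, 1, 5, seed=0, n_restarts=2)
        assert model.n_components == 1
        assert len(trace) == 5

    def test_planted_clusters_recovered(self, rng):
        centers = np.array([(i * 10.0, j * 10.0) for i in range(2) for j in range(2)])
        pts = np.vstack(
            [rng.normal(loc=c, scale=1.0, size=(80, 2)) for c in centers]
        )
        model, trace = select_k(pts, 2, 7, seed=0, n_restarts=3)
        assert model.n_components == 4
        # mean recovery, Hungarian-matched
        d = np.linalg.norm(model.means[:, None, :] - centers[None, :, :], axis=2)
        r, c = linear_sum_assignment(d)
        assert d[r, c].max() < 1.0

    def test_trace_bookkeeping(self, rng):
        pts = rng.normal(size=(50, 2))
        _, trace = select_k(pts, 2, 6, seed=0, n_restarts=1)
        assert [t["k"] for t in trace] == [2, 3, 4, 5, 6]
        assert all(("bic" in t) or ("error" in t) for t in trace)


class TestAssignClusters:
    def test_k1_all_zero_labels(self, rng):
        model = make_model([1.0], [[0, 0]], [I2])
        for rule in ("paper_ratio", "map"):
            a = assign_clusters(rng.normal(size=(5, 2)), model, rule=rule)
            assert np.all(a.labels == 0)

    def test_equal_mass_rules_agree(self, rng):
        # mirror-symmetric points around a symmetric model: masses exactly equal
        model = make_model([0.5, 0.5], [[-3, 0], [3, 0]], [I2, I2])
        half = rng.normal(loc=(-3, 0), size=(20, 2))
        pts = np.vstack([half, -half])
        ratio = assign_clusters(pts, model, rule="paper_ratio")
        mapr = assign_clusters(pts, model, rule="map")
        assert ratio.cluster_mass[0] == pytest.approx(ratio.cluster_mass[1], rel=1e-9)
        assert np.array_equal(ratio.labels, mapr.labels)

    def test_ratio_rule_matches_brute_force(self):
        """Hand-built responsibilities with unequal masses."""
        resp = np.array(
            [[0.9, 0.1], [0.6, 0.4], [0.8, 0.2], [0.55, 0.45]]
        )
        mass = resp.sum(axis=0)  # [2.85, 1.15]
        expected = np.argmax(resp / mass, axis=1)
        # ratio flips the low-mass cluster for borderline points
        a = ClusterAssignment(np.argmax(resp, axis=1), resp, mass)
        got = np.argmax(a.responsibilities / a.cluster_mass[None, :], axis=1)
        assert np.array_equal(got, expected)
        assert not np.array_equal(expected, np.argmax(resp, axis=1))

    def test_rules_differ_when_masses_skewed(self, rng):
        model = make_model([0.95, 0.05], [[0, 0], [4, 0]], [I2, I2])
        pts = rng.normal(loc=(2, 0), size=(200, 2))
        ratio = assign_clusters(pts, model, rule="paper_ratio")
        mapr = assign_clusters(pts, model, rule="map")
        assert (ratio.labels == 1).sum() >= (mapr.labels == 1).sum()


class TestEllipses:
    def test_identity_cov_radius(self):
        model = make_model([1.0], [[5, 6]], [I2])
        (e,) = cluster_ellipses(model, coverage=0.95)
        assert np.allclose(e["semi_axes"], 2.44774683, atol=1e-6)
        assert e["center"] == [5.0, 6.0]

    def test_diagonal_cov_axes(self):
        model = make_model([1.0], [[0, 0]], [np.diag([4.0, 1.0])])
        (e,) = cluster_ellipses(model, coverage=0.95)
        ax = e["semi_axes"]
        assert ax[0] / ax[1] == pytest.approx(2.0, abs=1e-9)
        assert abs(np.cos(e["angle"])) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_coverage(self, rng):
        cov = np.array([[4.0, 1.2], [1.2, 2.0]])
        model = make_model([1.0], [[0, 0]], [cov])
        (e,) = cluster_ellipses(model, coverage=0.95)
        pts = rng.multivariate_normal([0, 0], cov, size=10_000)
        inv = np.linalg.inv(cov)
        from scipy.stats import chi2

        maha = np.einsum("ni,ij,nj->n", pts, inv, pts)
        inside = (maha <= chi2.ppf(0.95, 2)).mean()
        assert inside == pytest.approx(0.95, abs=0.02)

    def test_bad_coverage(self):
        model = make_model([1.0], [[0, 0]], [I2])
        with pytest.raises(ValueError):
            cluster_ellipses(model, coverage=1.5)
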