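import numpy as np
import pytest
from scipy import stats

from metabopca import (
    FitOptions,
    align_loadings,
    fit_ppca,
    generate_ppca,
    log_likelihood,
    posterior_latent,
    ppca_closed_form,
    preprocess,
)
from metabopca.ppca import PPCAModel

from conftest import dataset_from, dataset_with_covariance


class TestClosedForm:
    def test_noiseless_planar_data_recovers_plane(self, rng):
        # points exactly on a 2-plane plus a mean: sigma2 -> 0, span(W) = plane
        basis, _ = np.linalg.qr(rng.standard_normal((10, 2)))
        U = rng.standard_normal((40, 2)) * [3.0, 1.5]
        mu = rng.standard_normal(10)
        data = dataset_from(U @ basis.T + mu)
        model = ppca_closed_form(data, 2)
        assert model.sigma2 <= 1e-10
        # principal angles between span(W) and the plane
        Qw, _ = np.linalg.qr(model.W)
        angles = np.arccos(np.clip(np.linalg.svd(Qw.T @ basis)[1], -1, 1))
        assert angles.max() < 1e-8

    def test_isotropic_covariance_leaves_no_signal(self, rng):
        data = dataset_with_covariance(np.eye(4), 60, rng)
        model = ppca_closed_form(data, 1)
        assert np.linalg.norm(model.W) < 1e-6

    def test_known_eigenvalues_five_three_one_one(self, rng):
        # independent oracle: eigendecomposition done here with numpy on a
        # covariance constructed to have eigenvalues {5, 3, 1, 1}
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        C = Q @ np.diag([5.0, 3.0, 1.0, 1.0]) @ Q.T
        data = dataset_with_covariance(C, 50, rng)
        model = ppca_closed_form(data, 2)
        assert model.sigma2 == pytest.approx(1.0, abs=1e-8)
        norms = np.linalg.norm(model.W, axis=0)
        np.testing.assert_allclose(norms, [2.0, np.sqrt(2.0)], atol=1e-8)

    def test_q_exceeding_rank_rejected(self, rng):
        # rank-2 data (outer product construction) cannot support q = 3
        X = rng.standard_normal((8, 2)) @ rng.standard_normal((2, 10))
        with pytest.raises(ValueError, match="rank"):
            ppca_closed_form(dataset_from(X), 3)

    def test_matches_sklearn_pca(self, rng):
        # independent cross-check against an external implementation
        sk = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((30, 8)) * np.linspace(3, 0.5, 8)
        data = dataset_from(X)
        model = ppca_closed_form(data, 3)
        pca = sk.PCA(n_components=3).fit(X)
        # sklearn uses the 1/(n-1) divisor; rescale its eigenvalues
        lam = pca.explained_variance_ * (29 / 30)
        s2 = pca.noise_variance_ * (29 / 30)
        expected = pca.components_.T * np.sqrt(lam - s2)
        aligned = align_loadings(model.W, expected, sign_only=True)
        np.testing.assert_allclose(aligned, expected, atol=1e-8)
        assert model.sigma2 == pytest.approx(s2, rel=1e-8)


class TestEMFit:
    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_em_matches_closed_form_oracle(self, q):
        data, _ = generate_ppca(50, 20, 3, sigma2=0.5, seed=11)
        dc = preprocess(data)
        oracle = ppca_closed_form(dc, q)
        fit = fit_ppca(dc, q, FitOptions(init="random", seed=5, tol=1e-8, max_iter=5000))
        W = align_loadings(fit.model.W, oracle.W, sign_only=True)
        assert np.abs(W - oracle.W).max() < 1e-4
        assert abs(fit.model.sigma2 - oracle.sigma2) / oracle.sigma2 < 1e-4

    def test_loglik_trace_monotone(self):
        data, _ = generate_ppca(40, 15, 2, seed=3)
        fit = fit_ppca(preprocess(data), 2, FitOptions(init="random", seed=1))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_random_inits_reach_same_optimum(self):
        data, _ = generate_ppca(60, 12, 2, seed=9)
        dc = preprocess(data)
        lls = [
            fit_ppca(dc, 2, FitOptions(init="random", seed=s, tol=1e-7)).loglik
            for s in (1, 2)
        ]
        assert abs(lls[0] - lls[1]) < 1e-4

    def test_final_loglik_equals_log_likelihood_function(self):
        data, _ = generate_ppca(30, 10, 2, seed=4)
        dc = preprocess(data)
        fit = fit_ppca(dc, 2)
        assert fit.loglik == pytest.approx(log_likelihood(fit.model, dc), abs=1e-6)


class TestLogLikelihood:
    def test_zero_loadings_reduce_to_isotropic_gaussian(self, rng):
        p, n = 5, 20
        X = rng.standard_normal((n, p))
        mu = rng.standard_normal(p)
        model = PPCAModel(W=np.zeros((p, 2)), mu=mu, sigma2=1.7)
        expected = stats.norm.logpdf(X, loc=mu, scale=np.sqrt(1.7)).sum()
        assert log_likelihood(model, dataset_from(X)) == pytest.approx(expected)

    def test_matches_dense_multivariate_normal(self, rng):
        p, q = 3, 1
        W = rng.standard_normal((p, q))
        mu = rng.standard_normal(p)
        X = rng.standard_normal((8, p))
        model = PPCAModel(W=W, mu=mu, sigma2=0.6)
        C = W @ W.T + 0.6 * np.eye(p)
        expected = stats.multivariate_normal.logpdf(X, mean=mu, cov=C).sum()
        assert log_likelihood(model, dataset_from(X)) == pytest.approx(expected)

    def test_duplicating_samples_doubles_loglik(self, rng):
        W = rng.standard_normal((4, 2))
        model = PPCAModel(W=W, mu=np.zeros(4), sigma2=1.0)
        X = rng.standard_normal((6, 4))
        ll1 = log_likelihood(model, dataset_from(X))
        ll2 = log_likelihood(model, dataset_from(np.vstack([X, X])))
        assert ll2 == pytest.approx(2 * ll1)

    def test_mle_beats_perturbed_parameters(self, rng):
        data, _ = generate_ppca(40, 8, 2, seed=21)
        dc = preprocess(data)
        model = ppca_closed_form(dc, 2)
        ll_star = log_likelihood(model, dc)
        for _ in range(100):
            pert = PPCAModel(
                W=model.W + 0.05 * rng.standard_normal(model.W.shape),
                mu=model.mu + 0.05 * rng.standard_normal(model.p),
                sigma2=model.sigma2 * np.exp(0.1 * rng.standard_normal()),
            )
            assert log_likelihood(pert, dc) <= ll_star + 1e-9


class TestPosterior:
    def test_noiseless_limit_is_least_squares_projection(self, rng):
        W = rng.standard_normal((6, 2))
        X = rng.standard_normal((10, 6))
        model = PPCAModel(W=W, mu=np.zeros(6), sigma2=1e-12)
        post = posterior_latent(model, dataset_from(X))
        expected = X @ W @ np.linalg.inv(W.T @ W)
        np.testing.assert_allclose(post.means, expected, atol=1e-8)
        assert np.abs(post.covariance).max() < 1e-10

    def test_orthonormal_loadings_unit_noise_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        X = rng.standard_normal((7, 5))
        model = PPCAModel(W=Q, mu=np.zeros(5), sigma2=1.0)
        post = posterior_latent(model, dataset_from(X))
        np.testing.assert_allclose(post.means, X @ Q / 2.0, atol=1e-12)
        np.testing.assert_allclose(post.covariance, np.eye(2) / 2.0, atol=1e-12)

    def test_matches_dense_gaussian_conditioning(self, rng):
        # joint (u, x) Gaussian conditioning computed densely as the oracle
        p, q = 5, 2
        W = rng.standard_normal((p, q))
        mu = rng.standard_normal(p)
        sigma2 = 0.8
        X = rng.standard_normal((6, p))
        model = PPCAModel(W=W, mu=mu, sigma2=sigma2)
        post = posterior_latent(model, dataset_from(X))
        C = W @ W.T + sigma2 * np.eye(p)
        gain = W.T @ np.linalg.inv(C)
        np.testing.assert_allclose(post.means, (X - mu) @ gain.T, atol=1e-10)
        np.testing.assert_allclose(
            post.covariance, np.eye(q) - gain @ W, atol=1e-10
        )

    def test_posterior_covariance_shrinks_with_noise(self, rng):
        W = rng.standard_normal((6, 2))
        X = rng.standard_normal((4, 6))
        prev = None
        for s2 in [2.0, 1.0, 0.5, 0.1]:
            model = PPCAModel(W=W, mu=np.zeros(6), sigma2=s2)
            cov = posterior_latent(model, dataset_from(X)).covariance
            if prev is not None:
                # Loewner order via eigenvalues of the difference
                assert np.linalg.eigvalsh(prev - cov).min() > -1e-12
            prev = cov

    def test_ellipse_area_matches_level(self, rng):
        W = rng.standard_normal((5, 2))
        model = PPCAModel(W=W, mu=np.zeros(5), sigma2=1.0)
        post = posterior_latent(model, dataset_from(rng.standard_normal((3, 5))), level=0.95)
        a, b = post.ellipses[0]["semi_axes"]
        cov_evals = np.linalg.eigvalsh(post.covariance)
        expected = stats.chi2.ppf(0.95, 2) * cov_evals
        np.testing.assert_allclose(sorted([a**2, b**2]), sorted(expected), rtol=1e-10)


class TestAlignment:
    def test_identity_when_reference_equals_w(self, rng):
        W = rng.standard_normal((8, 3))
        np.testing.assert_allclose(align_loadings(W, W), W, atol=1e-10)

    def test_sign_flip_recovered(self, rng):
        W = rng.standard_normal((8, 3))
        flipped = W * np.array([1.0, -1.0, 1.0])
        out = align_loadings(flipped, W, sign_only=True)
        np.testing.assert_array_equal(out, W)

    def test_rotation_recovered_by_procrustes(self, rng):
        W = rng.standard_normal((10, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        out = align_loadings(W @ R, W)
        assert np.linalg.norm(out - W) < 1e-10
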