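import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from demobo import (
    GPHyperparameters,
    KernelSpec,
    TrainingSet,
    factorize,
    fit_hyperparameters,
    log_marginal_likelihood,
    predict,
    predict_batch,
    standardize_observations,
)
from conftest import sample_gp_observations


def make_hyper(family="RBF", kappa=0.3, sigma2=1.0, noise=1e-4):
    return GPHyperparameters(KernelSpec(family, kappa, sigma2), noise)


def dense_conditioning_oracle(train, hyper, queries):
    """Posterior mean/variance by brute-force joint-Gaussian conditioning."""
    from demobo import kernel_matrix

    Ktt = kernel_matrix(hyper.kernel, train.inputs, train.inputs)
    A = Ktt + hyper.noise_variance * np.eye(train.n)
    Kqt = kernel_matrix(hyper.kernel, queries, train.inputs)
    Ainv = np.linalg.inv(A)
    mean = Kqt @ Ainv @ train.observations
    var = hyper.kernel.variance - np.einsum("ij,jk,ik->i", Kqt, Ainv, Kqt)
    return mean, var


class TestStandardize:
    def test_two_point_example(self):
        z, center, scale = standardize_observations([1.0, 3.0])
        assert center == pytest.approx(2.0)
        assert scale == pytest.approx(math.sqrt(2.0))
        np.testing.assert_allclose(z, [-0.70710678, 0.70710678])

    def test_single_point_fallback(self):
        z, center, scale = standardize_observations([5.0])
        assert (z, center, scale) == (pytest.approx([0.0]), 5.0, 1.0)

    def test_constant_fallback(self):
        z, center, scale = standardize_observations([2.0, 2.0, 2.0])
        np.testing.assert_array_equal(z, [0, 0, 0])
        assert (center, scale) == (2.0, 1.0)

    def test_output_has_zero_mean_unit_sample_sd(self, rng):
        y = rng.normal(3.0, 7.0, size=25)
        z, center, scale = standardize_observations(y)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)
        np.testing.assert_allclose(center + scale * z, y, rtol=1e-12)


class TestLogMarginalLikelihood:
    def test_scalar_zero_observation(self):
        train = TrainingSet([[0.5]], [0.0])
        lml = log_marginal_likelihood(train, make_hyper(sigma2=0.6, noise=0.4))
        assert lml == pytest.approx(-0.5 * math.log(2 * math.pi), rel=1e-9)

    def test_scalar_closed_form(self):
        y1, s2 = 1.7, 0.9 + 0.2
        train = TrainingSet([[0.1]], [y1])
        lml = log_marginal_likelihood(train, make_hyper(sigma2=0.9, noise=0.2))
        expected = -y1**2 / (2 * s2) - 0.5 * math.log(s2) - 0.5 * math.log(2 * math.pi)
        assert lml == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("family", ["Exponential", "Matern52", "RBF"])
    def test_matches_dense_multivariate_normal_density(self, family, rng):
        from demobo import kernel_matrix

        X = rng.random((6, 2))
        y = rng.normal(size=6)
        hyper = make_hyper(family, kappa=0.4, sigma2=1.3, noise=0.05)
        train = TrainingSet(X, y)
        K = kernel_matrix(hyper.kernel, X, X) + 0.05 * np.eye(6)
        oracle = multivariate_normal(mean=np.zeros(6), cov=K).logpdf(y)
        assert log_marginal_likelihood(train, hyper) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_permutation_invariance(self, rng):
        X = rng.random((7, 2))
        y = rng.normal(size=7)
        hyper = make_hyper(noise=0.01)
        perm = rng.permutation(7)
        a = log_marginal_likelihood(TrainingSet(X, y), hyper)
        b = log_marginal_likelihood(TrainingSet(X[perm], y[perm]), hyper)
        assert a == pytest.approx(b, abs=1e-8)


class TestFactorize:
    def test_scalar_alpha(self):
        gp = factorize(TrainingSet([[0.2]], [3.0]), make_hyper(sigma2=1.5, noise=0.0))
        assert gp.alpha[0] == pytest.approx(3.0 / 1.5)

    def test_cholesky_reconstructs_gram(self, rng):
        X = rng.random((9, 3))
        y = rng.normal(size=9)
        hyper = make_hyper("Matern52", 0.25, 2.0, 0.01)
        gp = factorize(TrainingSet(X, y), hyper)
        from demobo import kernel_matrix

        K = kernel_matrix(hyper.kernel, X, X) + (0.01 + gp.jitter) * np.eye(9)
        rel = np.linalg.norm(gp.chol @ gp.chol.T - K) / np.linalg.norm(K)
        assert rel < 1e-8

    def test_alpha_matches_dense_solve(self, rng):
        X = rng.random((8, 2))
        y = rng.normal(size=8)
        hyper = make_hyper(noise=0.1)
        gp = factorize(TrainingSet(X, y), hyper)
        from demobo import kernel_matrix

        direct = np.linalg.solve(
            kernel_matrix(hyper.kernel, X, X) + 0.1 * np.eye(8), y
        )
        np.testing.assert_allclose(gp.alpha, direct, atol=1e-8)


class TestPredict:
    def test_noiseless_interpolation(self, rng):
        X = rng.random((6, 2))
        y = rng.normal(size=6)
        gp = factorize(TrainingSet(X, y), make_hyper("Matern52", 0.5, 1.0, 0.0))
        for i in range(6):
            p = predict(gp, X[i])
            assert p.mean == pytest.approx(y[i], abs=1e-6)
            assert p.variance == pytest.approx(0.0, abs=1e-6)

    def test_single_point_closed_form(self):
        # RBF prior, one noiseless observation y=1 at t=0
        gp = factorize(TrainingSet([[0.0]], [1.0]), make_hyper("RBF", 1.0, 1.0, 0.0))
        for t in [0.1, 0.4, 0.9]:
            p = predict(gp, [t])
            assert p.mean == pytest.approx(math.exp(-t * t / 2), rel=1e-9)
            assert p.variance == pytest.approx(1 - math.exp(-t * t), rel=1e-8)

    @pytest.mark.parametrize("family", ["Exponential", "Matern32", "RBF"])
    def test_matches_dense_conditioning_oracle(self, family, rng):
        X = rng.random((8, 3))
        y = rng.normal(size=8)
        hyper = make_hyper(family, 0.35, 1.4, 0.02)
        train = TrainingSet(X, y)
        gp = factorize(train, hyper)
        Q = rng.random((5, 3))
        mean, var = predict_batch(gp, Q)
        om, ov = dense_conditioning_oracle(train, hyper, Q)
        np.testing.assert_allclose(mean, om, atol=1e-8)
        np.testing.assert_allclose(var, ov, atol=1e-8)

    def test_destandardization_round_trip(self, rng):
        X = rng.random((10, 1))
        y = rng.normal(50.0, 4.0, size=10)
        z, center, scale = standardize_observations(y)
        gp = factorize(
            TrainingSet(X, z), make_hyper(noise=0.0), standardization=(center, scale)
        )
        for i in range(10):
            assert predict(gp, X[i]).mean == pytest.approx(y[i], abs=1e-5)

    def test_posterior_variance_never_exceeds_prior(self, rng):
        X = rng.random((12, 2))
        y = rng.normal(size=12)
        hyper = make_hyper("Matern32", 0.3, 2.0, 0.05)
        gp = factorize(TrainingSet(X, y), hyper)
        _, var = predict_batch(gp, rng.random((50, 2)))
        assert np.all(var <= 2.0 + 1e-8)

    def test_adding_data_never_increases_variance(self, rng):
        X = rng.random((10, 2))
        y = rng.normal(size=10)
        hyper = make_hyper("RBF", 0.4, 1.0, 0.01)
        Q = rng.random((20, 2))
        _, var_small = predict_batch(factorize(TrainingSet(X[:6], y[:6]), hyper), Q)
        _, var_full = predict_batch(factorize(TrainingSet(X, y), hyper), Q)
        assert np.all(var_full <= var_small + 1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        gp = factorize(TrainingSet(rng.random((4, 2)), rng.normal(size=4)), make_hyper())
        with pytest.raises(ValueError):
            predict(gp, [0.5, 0.5, 0.5])


class TestFitHyperparameters:
    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            fit_hyperparameters(TrainingSet([[0.5]], [1.0]), "RBF")

    def test_fitted_lml_beats_heuristic_start(self, rng):
        X = rng.random((20, 1))
        y = np.sin(6 * X[:, 0]) + 0.1 * rng.normal(size=20)
        train = TrainingSet(X, y)
        hyper = fit_hyperparameters(train, "RBF", n_restarts=5, rng=rng)
        heuristic = GPHyperparameters(KernelSpec("RBF", 0.3, 1.0), 1e-4)
        assert log_marginal_likelihood(train, hyper) >= log_marginal_likelihood(
            train, heuristic
        ) - 1e-8

    def test_recovers_length_scale_from_known_gp(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.random((60, 1))
            y = sample_gp_observations(X, KernelSpec("RBF", 0.2, 1.0), 1e-4, rng)
            hyper = fit_hyperparameters(TrainingSet(X, y), "RBF", n_restarts=5, rng=rng)
            if 0.1 <= hyper.kernel.length_scale <= 0.4:
                hits += 1
        assert hits >= 16

    def test_variance_scale_equivariance(self):
        rng = np.random.default_rng(42)
        X = rng.random((60, 1))
        y = sample_gp_observations(X, KernelSpec("RBF", 0.2, 1.0), 1e-4, rng)
        h1 = fit_hyperparameters(
            TrainingSet(X, y), "RBF", n_restarts=5, rng=np.random.default_rng(1)
        )
        h2 = fit_hyperparameters(
            TrainingSet(X, 2 * y), "RBF", n_restarts=5, rng=np.random.default_rng(1)
        )
        ratio = h2.kernel.variance / h1.kernel.variance
        assert ratio == pytest.approx(4.0, rel=0.2)
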