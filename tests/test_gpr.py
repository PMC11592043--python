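import numpy as np
import pytest
from scipy.linalg import cholesky, cho_solve

from poptraj.errors import DataError, FitError
from poptraj.gpr import (
    GPRModel,
    fit_gpr,
    predict,
    rbf_kernel,
    smooth_population_velocities,
)

from conftest import chain_populations, make_dataset


def make_model(X, Y, sigma, length_scale, sigma_rbf, jitter=0.0):
    """Assemble a GPRModel with fixed hyperparameters (no fitting)."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    y_mean = Y.mean(axis=0)
    K = rbf_kernel(X, X, length_scale, sigma_rbf) + (sigma**2 + jitter) * np.eye(len(X))
    L = cholesky(K, lower=True)
    alpha = cho_solve((L, True), Y - y_mean)
    return GPRModel(X_train=X, y_mean=y_mean, sigma_noise=sigma,
                    length_scale=length_scale, sigma_rbf=sigma_rbf,
                    L=L, alpha=alpha, jitter=jitter)


def naive_posterior(X, Y, Xq, sigma, length_scale, sigma_rbf):
    """Dense textbook posterior: mean and variance via explicit inverse."""
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    mu_v = Y.mean(axis=0)
    S = rbf_kernel(X, X, length_scale, sigma_rbf) + sigma**2 * np.eye(len(X))
    Sinv = np.linalg.inv(S)
    Ks = rbf_kernel(Xq, X, length_scale, sigma_rbf)
    Kss = rbf_kernel(Xq, Xq, length_scale, sigma_rbf)
    mu = mu_v + Ks @ Sinv @ (Y - mu_v)
    cov = Kss + sigma**2 * np.eye(len(np.atleast_2d(Xq))) - Ks @ Sinv @ Ks.T
    return mu, np.diag(cov)


class TestKernel:
    def test_zero_distance_is_signal_variance(self):
        K = rbf_kernel([[1.0, 2.0]], [[1.0, 2.0]], length_scale=3.0, sigma_rbf=1.5)
        assert K[0, 0] == pytest.approx(1.5**2)

    def test_far_field_vanishes(self):
        K = rbf_kernel([[0.0]], [[1e4]], length_scale=1.0, sigma_rbf=1.0)
        assert K[0, 0] == 0.0

    def test_hand_evaluated_entry(self):
        K = rbf_kernel([[0.0]], [[2.0]], length_scale=1.0, sigma_rbf=1.0)
        assert K[0, 0] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(FitError):
            rbf_kernel([[0.0]], [[1.0]], length_scale=0.0, sigma_rbf=1.0)


class TestFit:
    def test_zero_targets_give_zero_posterior_mean(self):
        X = np.linspace(0, 1, 8)[:, None]
        model = fit_gpr(X, np.zeros((8, 2)), seed=0)
        mu, _ = predict(model, [[0.37], [0.9]])
        np.testing.assert_allclose(mu, 0.0, atol=1e-8)

    def test_conflicting_duplicates_force_noise(self):
        X = np.array([[0.0], [0.0], [1.0]])
        Y = np.array([[0.0], [1.0], [0.5]])
        model = fit_gpr(X, Y, seed=0)
        assert model.sigma_noise > 1e-3

    def test_noiseless_sine_interpolates_held_out_points(self):
        Xtr = np.linspace(0, 2 * np.pi, 10)[:, None]
        model = fit_gpr(Xtr, np.sin(Xtr[:, 0]), restarts=3, seed=0)
        Xte = np.linspace(0.3, 2 * np.pi - 0.3, 25)[:, None]
        mu, _ = predict(model, Xte)
        rmse = np.sqrt(np.mean((mu[:, 0] - np.sin(Xte[:, 0])) ** 2))
        assert rmse < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_gpr(np.zeros((1, 1)), np.zeros((1, 1)))


class TestPredict:
    def test_near_noiseless_interpolation_at_training_inputs(self):
        X = np.array([[0.0], [1.0], [2.5]])
        Y = np.array([[1.0], [-0.5], [2.0]])
        model = make_model(X, Y, sigma=1e-8, length_scale=1.0, sigma_rbf=1.0,
                           jitter=1e-12)
        mu, _ = predict(model, X)
        np.testing.assert_allclose(mu, Y, atol=1e-6)

    def test_far_query_reverts_to_prior_mean(self):
        X = np.array([[0.0], [1.0]])
        Y = np.array([[3.0], [5.0]])
        model = make_model(X, Y, sigma=0.1, length_scale=1.0, sigma_rbf=1.0)
        mu, var = predict(model, [[1e4]])
        np.testing.assert_allclose(mu, Y.mean(), atol=1e-6)
        assert var[0] == pytest.approx(1.0 + 0.1**2)

    def test_two_point_linear_solve_oracle(self):
        # train (0 -> 0), (2 -> 1); l=1, sigma_rbf=1, sigma=0.1; query x=1
        X = np.array([[0.0], [2.0]])
        Y = np.array([0.0, 1.0])
        model = make_model(X, Y, sigma=0.1, length_scale=1.0, sigma_rbf=1.0)
        mu, _ = predict(model, [[1.0]])
        S = np.array([[1.01, np.exp(-2)], [np.exp(-2), 1.01]])
        ks = np.array([np.exp(-0.5), np.exp(-0.5)])
        expected = 0.5 + ks @ np.linalg.solve(S, Y - 0.5)
        assert mu[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_posterior_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = int(rng.integers(3, 11))
            X = rng.uniform(-2, 2, size=(m, 2))
            Y = rng.normal(size=(m, 3))
            Xq = rng.uniform(-2, 2, size=(4, 2))
            s, l, srbf = 0.3, 1.2, 0.9
            model = make_model(X, Y, s, l, srbf)
            mu, var = predict(model, Xq)
            mu0, var0 = naive_posterior(X, Y, Xq, s, l, srbf)
            np.testing.assert_allclose(mu, mu0, atol=1e-8)
            np.testing.assert_allclose(var, var0, atol=1e-8)

    def test_variance_nonnegative_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(12, 1))
        Y = np.sin(4 * X[:, 0])
        Xq = rng.uniform(size=(6, 1))
        model = make_model(X, Y, 0.05, 0.4, 1.0)
        mu, var = predict(model, Xq)
        assert (var >= 0).all()
        perm = rng.permutation(12)
        model_p = make_model(X[perm], Y[perm], 0.05, 0.4, 1.0)
        mu_p, var_p = predict(model_p, Xq)
        np.testing.assert_allclose(mu, mu_p, atol=1e-10)
        np.testing.assert_allclose(var, var_p, atol=1e-10)

    def test_growing_noise_shrinks_posterior_toward_prior_mean(self):
        X = np.array([[0.0], [1.0], [2.0]])
        Y = np.array([0.0, 2.0, 0.0])
        query = [[1.0]]
        prior = Y.mean()
        pulls = []
        for s in [0.01, 0.1, 1.0, 10.0]:
            model = make_model(X, Y, s, 1.0, 1.0)
            mu, _ = predict(model, query)
            pulls.append(abs(mu[0, 0] - prior))
        assert pulls == sorted(pulls, reverse=True)

    def test_dimension_mismatch_rejected(self):
        model = make_model(np.zeros((3, 2)), np.zeros(3), 0.1, 1.0, 1.0, jitter=1e-8)
        with pytest.raises(DataError):
            predict(model, [[1.0]])


class TestPopulationSmoothing:
    def test_constant_velocity_cluster_is_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        V = np.tile([1.0, -2.0, 0.5], (30, 1))
        ds = make_dataset(X, V=V)
        pops = chain_populations(
            [X[:15].mean(0), X[15:].mean(0)], [None, None], [range(15), range(15, 30)]
        )
        for p in pops:
            p.velocity = None
        out = smooth_population_velocities(ds, pops, seed=0)
        for p in out:
            np.testing.assert_allclose(p.velocity, [1.0, -2.0, 0.5], atol=1e-6)

    def test_linear_velocity_field_recovered_at_centroids(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 4, size=(60, 1))
        ds = make_dataset(x, V=2 * x)
        pops = chain_populations(
            [x[:30].mean(0), x[30:].mean(0)], [None, None], [range(30), range(30, 60)]
        )
        out = smooth_population_velocities(ds, pops, mode="global", seed=0)
        for p in out:
            assert abs(p.velocity[0] - 2 * p.centroid[0]) < 0.1

    def test_tiny_cluster_falls_back_to_mean_velocity(self):
        X = np.array([[0.0, 0.0]])
        V = np.array([[3.0, 4.0]])
        ds = make_dataset(X, V=V)
        pops = chain_populations([X[0]], [None], [[0]])
        out = smooth_population_velocities(ds, pops, seed=0)
        np.testing.assert_allclose(out[0].velocity, [3.0, 4.0])
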