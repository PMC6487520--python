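import numpy as np
import pytest

from seedbo.gp_model import (GPFit, KernelHyperparams, fit_mle, kernel_cross,
                             kernel_eval, kernel_matrix, log_marginal_likelihood,
                             matern52)
from seedbo.parameter_space import ValidationError


def _matern_bessel(r, nu=2.5):
    """Textbook Matern correlation via the modified Bessel function."""
    from scipy.special import gamma, kv
    r = np.asarray(r, float)
    out = np.ones_like(r)
    nz = r > 0
    t = np.sqrt(2 * nu) * r[nz]
    out[nz] = (2 ** (1 - nu) / gamma(nu)) * t**nu * kv(nu, t)
    return out


def _dense_predict(h, X, y, mean, Xq, floors=None):
    """Brute-force predictive equations with an explicit matrix inverse."""
    n = len(y)
    diag = np.full(n, h.noise) if floors is None else np.maximum(h.noise, floors)
    K = kernel_cross(X, X, h) + np.diag(diag + 1e-10)
    Kinv = np.linalg.inv(K)
    Ks = kernel_cross(Xq, X, h)
    mu = mean + Ks @ Kinv @ (y - mean)
    var = h.amplitude - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mu, np.sqrt(np.clip(var, 0, None))


class TestKernel:
    def test_matches_bessel_form_of_matern(self, rng):
        r = rng.uniform(1e-3, 5.0, 50)
        assert np.max(np.abs(matern52(r) - _matern_bessel(r))) < 1e-12

    def test_zero_distance_gives_amplitude(self):
        h = KernelHyperparams(2.5, 0.3, 0.1)
        assert kernel_eval([0.2, 0.2], [0.2, 0.2], h) == pytest.approx(2.5)
        assert kernel_eval([0.2], [0.2], h, same_index=True) == pytest.approx(2.6)

    def test_vanishes_at_large_distance(self):
        h = KernelHyperparams(1.0, 0.1, 0.01)
        assert kernel_eval([0.0], [100.0], h) < 1e-12

    def test_dimension_mismatch_rejected(self):
        h = KernelHyperparams(1.0, 0.1, 0.01)
        with pytest.raises(ValidationError):
            kernel_eval([0.0, 0.1], [0.0], h)

    def test_hyperparams_must_sit_inside_bounds(self):
        with pytest.raises(ValidationError):
            KernelHyperparams(1.0, 0.3, 1e-4)   # below default 0.01 noise floor


class TestPredict:
    def test_matches_dense_inverse_oracle(self, rng):
        for _ in range(5):
            n, d = rng.integers(3, 30), rng.integers(1, 5)
            X = rng.uniform(0, 1, (n, d))
            y = rng.normal(0, 1, n)
            h = KernelHyperparams(float(rng.uniform(0.1, 3)),
                                  float(rng.uniform(0.05, 1)),
                                  float(rng.uniform(0.01, 0.5)))
            fit = GPFit(h, float(y.mean()), X, y)
            Xq = rng.uniform(0, 1, (7, d))
            mu, sd = fit.predict(Xq)
            mu0, sd0 = _dense_predict(h, X, y, float(y.mean()), Xq)
            assert np.max(np.abs(mu - mu0) / np.maximum(1e-12, np.abs(mu0))) < 1e-8
            assert np.max(np.abs(sd - sd0)) < 1e-8

    def test_matches_sklearn_reference(self, rng):
        """Independent route: sklearn GP with the same fixed kernel.

        sklearn's predictive variance includes the white-noise term, ours is
        the latent-response variance, so the comparison adds it back.
        """
        pytest.importorskip("sklearn")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import (ConstantKernel, Matern,
                                                      WhiteKernel)
        X = rng.uniform(0, 1, (12, 3))
        y = rng.normal(0.5, 0.3, 12)
        h = KernelHyperparams(0.8, 0.25, 0.04)
        fit = GPFit(h, float(y.mean()), X, y)
        k = (ConstantKernel(h.amplitude, "fixed")
             * Matern(h.length_scale, "fixed", nu=2.5)
             + WhiteKernel(h.noise, "fixed"))
        ref = GaussianProcessRegressor(kernel=k, alpha=0.0, optimizer=None)
        ref.fit(X, y - y.mean())
        Xq = rng.uniform(0, 1, (6, 3))
        mu, sd = fit.predict(Xq)
        mu_ref, sd_ref = ref.predict(Xq, return_std=True)
        assert np.allclose(mu, mu_ref + y.mean(), atol=1e-8)
        assert np.allclose(sd**2 + h.noise, sd_ref**2, atol=1e-8)

    def test_far_query_reverts_to_prior(self, toy_fit_1d):
        mu, sd = toy_fit_1d.predict_one([50.0])
        assert mu == pytest.approx(toy_fit_1d.mean, abs=1e-9)
        assert sd**2 == pytest.approx(toy_fit_1d.hyperparams.amplitude, abs=1e-9)

    def test_interpolates_with_tiny_noise(self, rng):
        X = rng.uniform(0, 1, (8, 2))
        y = rng.normal(0, 0.5, 8)
        h = KernelHyperparams(1.0, 0.4, 1e-9, noise_bounds=(1e-10, 1e5))
        fit = GPFit(h, float(y.mean()), X, y)
        mu, _ = fit.predict(X)
        assert np.max(np.abs(mu - y)) < 1e-6

    def test_replicates_with_disagreeing_targets(self):
        """Identical inputs with different targets: noise absorbs the spread
        and the prediction lands between the two."""
        X = np.array([[0.3], [0.3]])
        y = np.array([0.2, 0.8])
        fit = fit_mle(X, y, n_restarts=5, rng=np.random.default_rng(0))
        mu, _ = fit.predict_one([0.3])
        assert 0.2 <= mu <= 0.8

    def test_mean_shift_consistency(self, rng):
        X = rng.uniform(0, 1, (10, 2))
        y = rng.normal(0, 1, 10)
        h = KernelHyperparams(1.0, 0.3, 0.05)
        Xq = rng.uniform(0, 1, (4, 2))
        mu1, sd1 = GPFit(h, float(y.mean()), X, y).predict(Xq)
        c = 3.7
        mu2, sd2 = GPFit(h, float(y.mean() + c), X, y + c).predict(Xq)
        assert np.allclose(mu2, mu1 + c, atol=1e-10)
        assert np.allclose(sd2, sd1, atol=1e-12)

    def test_variance_shrinks_after_noiseless_observation_at_query(self, toy_fit_1d):
        xq = [0.6]
        _, sd_before = toy_fit_1d.predict_one(xq)
        mu, _ = toy_fit_1d.predict_one(xq)
        grown = toy_fit_1d.with_observation(xq, mu, floor=0.0)
        _, sd_after = grown.predict_one(xq)
        assert sd_after <= sd_before + 1e-12


class TestFitMLE:
    def test_requires_two_points_and_finite_targets(self):
        with pytest.raises(ValidationError):
            fit_mle(np.array([[0.0]]), np.array([1.0]))
        with pytest.raises(ValidationError):
            fit_mle(np.array([[0.0], [1.0]]), np.array([1.0, np.nan]))

    def test_returned_fit_beats_default_start(self, rng):
        X = rng.uniform(0, 1, (15, 2))
        y = np.sin(4 * X[:, 0]) + rng.normal(0, 0.1, 15)
        fit = fit_mle(X, y, n_restarts=10, rng=rng)
        start = KernelHyperparams(max(float(np.var(y)), 1e-5), 1.0, 0.01)
        assert fit.log_marginal_likelihood >= log_marginal_likelihood(
            start, X, y, float(y.mean())) - 1e-8

    def test_noise_respects_global_floor_bound(self, rng):
        X = rng.uniform(0, 1, (10, 1))
        y = np.linspace(0, 1, 10)   # nearly noiseless data
        fit = fit_mle(X, y, bounds=((1e-5, 1e5), (1e-5, 1e5), (0.01, 1e5)),
                      n_restarts=8, rng=rng)
        assert fit.hyperparams.noise >= 0.01 * (1 - 1e-9)

    def test_recovers_known_hyperparameters_within_factor_two(self):
        """Parameter recovery on data sampled from a known GP."""
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (40, 1))
        true = KernelHyperparams(1.0, 0.3, 0.05, noise_bounds=(1e-6, 1e5))
        K = kernel_matrix(X, true)
        y = np.linalg.cholesky(K) @ rng.standard_normal(40)
        fit = fit_mle(X, y, bounds=((1e-5, 1e5), (1e-5, 1e5), (1e-6, 1e5)),
                      n_restarts=30, rng=np.random.default_rng(1))
        h = fit.hyperparams
        for got, truth in [(h.amplitude, 1.0), (h.length_scale, 0.3),
                           (h.noise, 0.05)]:
            assert truth / 2 <= got <= truth * 2

    def test_per_obs_floors_enter_the_diagonal(self, rng):
        X = rng.uniform(0, 1, (8, 1))
        y = rng.normal(0.5, 0.2, 8)
        floors = np.full(8, 0.3)
        h = KernelHyperparams(1.0, 0.3, 0.01)
        lml_floored = log_marginal_likelihood(h, X, y, 0.5, floors)
        h_eq = KernelHyperparams(1.0, 0.3, 0.3)
        assert lml_floored == pytest.approx(
            log_marginal_likelihood(h_eq, X, y, 0.5), abs=1e-9)

    def test_serialization_round_trip(self, toy_fit_1d, tmp_path):
        path = tmp_path / "fit.json"
        toy_fit_1d.to_json(path)
        h = GPFit.hyperparams_from_json(path.read_text())
        assert h == toy_fit_1d.hyperparams
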