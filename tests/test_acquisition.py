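import numpy as np
import pytest

from seedbo.acquisition import (AcquisitionConfig, EmptySubsetError, exploit_metric,
                                explore_metric, maximize_ucb, select_kappa,
                                suggest_batch, ucb)
from seedbo.gp_model import GPFit, KernelHyperparams
from seedbo.parameter_space import ValidationError


def _fit_state(fit):
    """Byte-level snapshot of everything a fit caches."""
    return (fit.X.tobytes(), fit.y.tobytes(),
            None if fit.floors is None else fit.floors.tobytes(),
            fit._L.tobytes(), fit._alpha.tobytes(), fit.mean, fit.hyperparams)


class TestUCB:
    def test_kappa_zero_is_predictive_mean(self, toy_fit_1d):
        x = [0.4]
        mu, _ = toy_fit_1d.predict_one(x)
        assert ucb(toy_fit_1d, x, 0.0) == pytest.approx(mu, abs=1e-12)

    def test_arithmetic(self, toy_fit_1d):
        x = [0.37]
        mu, sd = toy_fit_1d.predict_one(x)
        assert ucb(toy_fit_1d, x, 2.0) == pytest.approx(mu + 2 * sd)

    def test_nondecreasing_in_kappa(self, toy_fit_1d):
        x = [0.6]
        vals = [ucb(toy_fit_1d, x, k) for k in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_independent_of_kappa_where_sd_vanishes(self, rng):
        X = np.array([[0.2], [0.8]])
        y = np.array([0.3, 0.7])
        h = KernelHyperparams(1.0, 0.3, 1e-12, noise_bounds=(1e-13, 1e5))
        fit = GPFit(h, 0.5, X, y)
        _, sd = fit.predict_one([0.2])
        assert sd < 2e-5   # only the stabilizing jitter remains
        assert ucb(fit, [0.2], 10.0) == pytest.approx(ucb(fit, [0.2], 0.0),
                                                      abs=10 * sd + 1e-12)

    def test_negative_kappa_rejected(self, toy_fit_1d):
        with pytest.raises(ValidationError):
            ucb(toy_fit_1d, [0.1], -1.0)


class TestDistanceMetrics:
    def test_exploit_zero_at_observed_point(self):
        obs = np.array([[0.2, 0.4]])
        assert exploit_metric([0.2, 0.4], obs, [0.01, 0.01]) == 0.0

    def test_exploit_boundary_is_one(self):
        obs = np.array([[0.2, 0.4]])
        assert exploit_metric([0.21, 0.4], obs, [0.01, 0.01]) == pytest.approx(1.0)

    def test_exploit_vacuous_without_observations(self):
        assert exploit_metric([0.5], np.empty((0, 1)), [0.01]) == np.inf

    def test_explore_zero_at_subset_point_is_feasible(self):
        sub = np.array([[0.3, 0.3]])
        assert explore_metric([0.3, 0.3], sub, [0.25, 0.25]) == 0.0

    def test_explore_boundary_is_one(self):
        sub = np.array([[0.3, 0.3]])
        assert explore_metric([0.3 + 0.125, 0.3 + 0.125], sub,
                              [0.25, 0.25]) == pytest.approx(1.0)

    def test_empty_subset_raises_with_guidance(self):
        with pytest.raises(EmptySubsetError, match="widen"):
            explore_metric([0.5], np.empty((0, 1)), [0.25])

    def test_metrics_match_brute_force_loops(self, rng):
        """Normalized min-over-points metrics vs explicit Python loops."""
        for _ in range(10):
            d = rng.integers(1, 5)
            pts = rng.uniform(0, 1, (rng.integers(1, 6), d))
            x = rng.uniform(0, 1, d)
            eps_i = rng.uniform(0.01, 0.3, d)
            eps_o = rng.uniform(0.1, 0.6, d)
            brute_inf = min(max(abs(x[k] - p[k]) / eps_i[k] for k in range(d))
                            for p in pts)
            brute_l1 = min(sum(abs(x[k] - p[k]) / eps_o[k] for k in range(d))
                           for p in pts)
            assert exploit_metric(x, pts, eps_i) == pytest.approx(brute_inf, rel=1e-12)
            assert explore_metric(x, pts, eps_o) == pytest.approx(brute_l1, rel=1e-12)


class TestMaximizeUCB:
    def test_unconstrained_matches_dense_grid_argmax(self, toy_fit_1d, space1d, rng):
        grid = np.linspace(0, 1, 10001)[:, None]
        for kappa in (0.0, 2.0):
            mu, sd = toy_fit_1d.predict(grid)
            gx = float(grid[np.argmax(mu + kappa * sd), 0])
            s = maximize_ucb(toy_fit_1d, kappa, space1d, constraints=False,
                             n_multistarts=8, rng=rng)
            assert abs(s.x_scaled[0] - gx) < 2e-3  # within grid + rounding step

    def test_exploit_constraint_contract(self, toy_fit_1d, space1d, rng):
        """With an observed point at the unconstrained argmax, the constrained
        suggestion keeps the required Chebyshev distance."""
        s0 = maximize_ucb(toy_fit_1d, 0.0, space1d, constraints=False, rng=rng)
        obs = np.vstack([toy_fit_1d.X, s0.x_scaled])
        s = maximize_ucb(toy_fit_1d, 0.0, space1d, observed=obs,
                         constraints=True, rng=rng)
        assert s.feasible
        assert s.exploit_slack >= 1 - 1e-6

    def test_large_kappa_seeks_uncertainty(self, space1d, rng):
        """With a uniform mean, huge kappa drives the choice to the region of
        largest predictive sd, far from the data cluster."""
        X = np.array([[0.1], [0.15], [0.2]])
        y = np.array([0.5, 0.5, 0.5])
        fit = GPFit(KernelHyperparams(1.0, 0.15, 0.01), 0.5, X, y)
        s = maximize_ucb(fit, 50.0, space1d, constraints=False, rng=rng)
        assert s.x_scaled[0] > 0.6

    def test_suggestion_is_precision_rounded(self, toy_fit_1d, space1d, rng):
        s = maximize_ucb(toy_fit_1d, 1.0, space1d, constraints=False, rng=rng)
        assert s.x[0] == pytest.approx(round(s.x[0], 1))


class TestSelectKappa:
    def test_returns_smallest_feasible_kappa(self, toy_fit_1d, space1d, rng):
        cfg = AcquisitionConfig(kappa="auto", kappa_grid=(0.0, 1.0, 2.0),
                                n_multistarts=6)
        # wide explore budget, observed points far from the bump: kappa=0 works
        obs = np.array([[0.0], [1.0]])
        kappa, s = select_kappa(toy_fit_1d, cfg, space1d, observed=obs,
                                explore_subset=toy_fit_1d.X, rng=rng)
        assert kappa == 0.0
        assert s.feasible

    def test_kappa_grows_when_exploitation_is_blocked(self, space1d, rng):
        """A mean-argmax sitting on an observed point forces a larger kappa."""
        X = np.array([[0.0], [0.5], [1.0]])
        y = np.array([0.0, 1.0, 0.0])
        fit = GPFit(KernelHyperparams(1.0, 0.25, 0.01), float(y.mean()), X, y)
        cfg = AcquisitionConfig(kappa="auto", kappa_grid=(0.0, 2.0, 8.0),
                                n_multistarts=8)
        kappa, s = select_kappa(fit, cfg, space1d, observed=X,
                                explore_subset=X, rng=rng)
        assert kappa > 0.0

    def test_agrees_with_exhaustive_grid_scan(self, space1d, rng):
        X = np.array([[0.0], [0.5], [1.0]])
        y = np.array([0.0, 1.0, 0.0])
        fit = GPFit(KernelHyperparams(1.0, 0.25, 0.01), float(y.mean()), X, y)
        grid = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
        cfg = AcquisitionConfig(kappa="auto", kappa_grid=grid, n_multistarts=8)
        kappa, _ = select_kappa(fit, cfg, space1d, observed=X, explore_subset=X,
                                rng=np.random.default_rng(7))
        feasible = []
        for k in grid:
            s = maximize_ucb(fit, k, space1d, observed=X, explore_subset=X,
                             constraints=False, n_multistarts=8,
                             rng=np.random.default_rng(7))
            if s.feasible:
                feasible.append(k)
        assert kappa == (feasible[0] if feasible else kappa)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            AcquisitionConfig(kappa="auto", kappa_grid=())


class TestSuggestBatch:
    def test_b1_matches_single_constrained_call(self, toy_fit_1d, space1d):
        cfg = AcquisitionConfig(kappa=1.0, batch_size=1, n_multistarts=6)
        before = _fit_state(toy_fit_1d)
        batch = suggest_batch(toy_fit_1d, cfg, space1d,
                              explore_subset=toy_fit_1d.X,
                              rng=np.random.default_rng(3))
        single = maximize_ucb(toy_fit_1d, 1.0, space1d,
                              explore_subset=toy_fit_1d.X, constraints=True,
                              n_multistarts=6, rng=np.random.default_rng(3))
        assert len(batch) == 1
        assert np.allclose(batch[0].x_scaled, single.x_scaled)
        assert _fit_state(toy_fit_1d) == before

    def test_batch_members_pairwise_exploit_feasible(self, toy_fit_1d, space1d):
        cfg = AcquisitionConfig(kappa=2.0, batch_size=3, n_multistarts=6)
        batch = suggest_batch(toy_fit_1d, cfg, space1d,
                              explore_subset=toy_fit_1d.X,
                              rng=np.random.default_rng(5))
        eps = space1d.eps_exploit_scaled
        for i in range(3):
            for j in range(i + 1, 3):
                if batch[j].feasible:
                    m = exploit_metric(batch[j].x_scaled,
                                       batch[i].x_scaled[None, :], eps)
                    assert m >= 1 - 1e-6

    def test_fantasy_targets_are_predictive_means(self, toy_fit_1d, space1d):
        """Re-derive the fantasy sequence: target j equals the mean of the fit
        conditioned on fantasies 0..j-1, and the caller's fit is untouched."""
        cfg = AcquisitionConfig(kappa=2.0, batch_size=3, n_multistarts=6,
                                fantasy_floor=0.01)
        before = _fit_state(toy_fit_1d)
        batch = suggest_batch(toy_fit_1d, cfg, space1d,
                              explore_subset=toy_fit_1d.X,
                              rng=np.random.default_rng(11))
        assert _fit_state(toy_fit_1d) == before   # fantasies fully retracted
        work = toy_fit_1d
        for s in batch:
            expect, _ = work.predict_one(s.x_scaled)
            work = work.with_observation(s.x_scaled, expect, 0.01)
            # the appended fantasy target is exactly that predictive mean
            assert work.y[-1] == pytest.approx(expect, abs=1e-12)
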