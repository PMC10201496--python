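"""Bayesian optimization: EI closed form, surrogate behavior, loop contracts."""

import numpy as np
import pytest

from borvm.bayesopt import (
    BOConfig,
    ContinuousDim,
    GPPosterior,
    SearchSpace,
    expected_improvement,
    fit_surrogate,
    kernel_search_space,
    optimize,
    propose_next,
)


@pytest.fixture()
def quadratic_space():
    return SearchSpace(continuous={"x": ContinuousDim(0.0, 1.0)})


class TestExpectedImprovement:
    def test_zero_when_no_possible_improvement(self):
        assert expected_improvement(0.7, 0.0, 0.5) == 0.0
        assert expected_improvement(0.5, 0.0, 0.5) == 0.0

    def test_deterministic_improvement(self):
        assert expected_improvement(0.3, 0.0, 0.5) == pytest.approx(0.2)

    def test_closed_form_at_mean_equal_incumbent(self):
        assert expected_improvement(0.5, 1.0, 0.5) == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_nonnegative_everywhere(self, rng):
        mu = rng.normal(size=200)
        sigma = rng.uniform(0, 2, size=200)
        assert (expected_improvement(mu, sigma, 0.0) >= 0).all()

    def test_increasing_in_sigma_at_incumbent_mean(self):
        sigmas = np.linspace(0.01, 2, 50)
        ei = expected_improvement(np.full_like(sigmas, 0.5), sigmas, 0.5)
        assert (np.diff(ei) > 0).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            expected_improvement(0.0, -1.0, 0.0)


class TestSearchSpace:
    def test_encode_decode_round_trip_on_grid(self):
        space = kernel_search_space()
        for family in space.categorical["family"]:
            for gamma in [1e-3, 1e-1, 10.0, 1e3]:
                for coef0 in [-5.0, 0.0, 5.0]:
                    for degree in [1, 3, 5]:
                        cfg = {"family": family, "gamma": gamma, "coef0": coef0, "degree": degree}
                        back = space.decode(space.encode(cfg))
                        assert back["family"] == family
                        assert back["gamma"] == pytest.approx(gamma, rel=1e-9)
                        assert back["coef0"] == pytest.approx(coef0, abs=1e-9)
                        assert back["degree"] == degree

    def test_samples_respect_bounds(self, rng):
        space = kernel_search_space()
        for _ in range(100):
            cfg = space.sample(rng)
            assert cfg["family"] in ("gaussian", "polynomial", "sigmoid", "laplacian")
            assert 1e-3 <= cfg["gamma"] <= 1e3
            assert -5.0 <= cfg["coef0"] <= 5.0
            assert 1 <= cfg["degree"] <= 5

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ContinuousDim(1.0, 1.0)
        with pytest.raises(ValueError):
            ContinuousDim(-1.0, 1.0, scale="log")


class TestSurrogate:
    def _history(self, rng, n=12):
        space = kernel_search_space()
        configs = [space.sample(rng) for _ in range(n)]
        ys = [0.2 + 0.1 * np.sin(i) for i in range(n)]
        return list(zip(configs, ys)), space

    def test_interpolates_observations(self, rng):
        history, space = self._history(rng)
        gp = fit_surrogate(history, space, seed=0)
        X = np.array([space.encode(c) for c, _ in history])
        mu, sigma = gp.predict(X)
        y = np.array([y for _, y in history])
        noise = np.exp(gp.theta[-1]) * gp.y_std + 0.05
        assert np.abs(mu - y).max() < 3 * noise + 0.05

    def test_uncertainty_smaller_at_observed_points(self, rng):
        history, space = self._history(rng)
        gp = fit_surrogate(history, space, seed=0)
        X = np.array([space.encode(c) for c, _ in history])
        _, sigma_obs = gp.predict(X)
        far = np.array([space.encode(space.sample(rng)) for _ in range(50)])
        _, sigma_far = gp.predict(far)
        assert sigma_obs.mean() <= sigma_far.max()

    def test_sigma_nonnegative_on_random_grid(self, rng):
        history, space = self._history(rng)
        gp = fit_surrogate(history, space, seed=0)
        grid = np.array([space.encode(space.sample(rng)) for _ in range(200)])
        _, sigma = gp.predict(grid)
        assert (sigma >= 0).all()

    def test_degenerate_history_falls_back_to_prior(self):
        space = SearchSpace(continuous={"x": ContinuousDim(0.0, 1.0)})
        history = [({"x": 0.5}, 0.1), ({"x": 0.5}, 0.2)]
        with pytest.warns(UserWarning, match="degenerate"):
            gp = fit_surrogate(history, space, seed=0)
        mu, sigma = gp.predict(np.array([[0.9]]))
        assert np.isfinite(mu).all() and (sigma > 0).all()

    def test_too_few_observations_rejected(self, quadratic_space):
        with pytest.raises(ValueError, match="at least 2"):
            fit_surrogate([({"x": 0.1}, 0.5)], quadratic_space)


class TestProposeNext:
    def test_valid_configuration_and_determinism(self, rng):
        space = kernel_search_space()
        history = [(space.sample(rng), 0.3), (space.sample(rng), 0.2), (space.sample(rng), 0.4)]
        gp = fit_surrogate(history, space, seed=0)
        cfg1 = propose_next(gp, space, np.random.default_rng(99), n_candidates=128)
        cfg2 = propose_next(gp, space, np.random.default_rng(99), n_candidates=128)
        assert cfg1 == cfg2
        assert cfg1["family"] in ("gaussian", "polynomial", "sigmoid", "laplacian")
        assert 1e-3 <= cfg1["gamma"] <= 1e3


class TestOptimize:
    def test_history_length_and_termination(self, quadratic_space):
        res = optimize(
            lambda c: (c["x"] - 0.3) ** 2, quadratic_space, BOConfig(n_init=2, max_iter=3, seed=0)
        )
        assert len(res.history) == 3
        assert res.termination_reason == "max_iter"

    def test_trace_non_increasing(self, quadratic_space):
        res = optimize(
            lambda c: (c["x"] - 0.3) ** 2, quadratic_space, BOConfig(n_init=4, max_iter=15, seed=3)
        )
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))
        assert res.best_objective == res.trace[-1]

    def test_target_fitness_stops_early(self, quadratic_space):
        res = optimize(
            lambda c: (c["x"] - 0.3) ** 2,
            quadratic_space,
            BOConfig(n_init=4, max_iter=50, seed=0, target_fitness=0.05),
        )
        assert res.termination_reason == "target_fitness"
        assert len(res.history) < 50

    def test_quadratic_recovery_over_seeds(self, quadratic_space):
        """Median |best_x - 0.3| over 10 seeds after 30 evaluations < 0.05."""
        errors = []
        for seed in range(10):
            res = optimize(
                lambda c: (c["x"] - 0.3) ** 2,
                quadratic_space,
                BOConfig(n_init=5, max_iter=30, seed=seed),
            )
            errors.append(abs(res.best_config["x"] - 0.3))
        assert np.median(errors) < 0.05

    def test_ei_not_dominated_by_random_search(self, quadratic_space):
        """EI acquisition should do at least as well as random search
        (median best objective over 10 seeds) on the quadratic benchmark."""
        best_ei, best_rand = [], []
        for seed in range(10):
            for use_ei, store in [(True, best_ei), (False, best_rand)]:
                res = optimize(
                    lambda c: (c["x"] - 0.3) ** 2,
                    quadratic_space,
                    BOConfig(n_init=5, max_iter=20, seed=seed, use_ei=use_ei),
                )
                store.append(res.best_objective)
        assert np.median(best_ei) <= np.median(best_rand)

    def test_failing_objective_recorded_with_penalty(self, quadratic_space):
        calls = {"n": 0}

        def objective(cfg):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return (cfg["x"] - 0.3) ** 2

        res = optimize(objective, quadratic_space, BOConfig(n_init=3, max_iter=5, seed=1))
        failed = [h for h in res.history if h[2]]
        assert len(failed) == 1
        ok_values = [h[1] for h in res.history if not h[2]]
        assert failed[0][1] > max(v for v in ok_values)
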