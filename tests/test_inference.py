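import numpy as np
import pytest
from scipy import stats as sps

from demicwave.inference import (
    Posterior2D,
    PosteriorGLM,
    ScenarioChoiceForest,
    _hdi_from_grid,
    glm_adjust,
    joint_posterior_2d,
    marginal_density_pvalue,
    prob_query,
    reject,
    relative_bias,
    rf_model_choice,
)


class TestReject:
    def test_retained_count(self, rng):
        stats = rng.normal(0, 1, (100_000, 3))
        keep = reject(stats, np.zeros(3), 0.01)
        assert len(keep) == 1000

    def test_exact_match_is_retained(self, rng):
        stats = rng.normal(0, 1, (500, 4))
        keep = reject(stats, stats[123], 0.01)
        assert 123 in keep

    def test_delta_one_keeps_all(self, rng):
        stats = rng.normal(0, 1, (50, 2))
        assert len(reject(stats, np.zeros(2), 1.0)) == 50

    def test_too_small_delta_rejected(self, rng):
        with pytest.raises(ValueError):
            reject(rng.normal(0, 1, (100, 2)), np.zeros(2), 0.001)

    def test_row_order_invariance_up_to_ties(self, rng):
        stats = rng.normal(0, 1, (400, 3))
        obs = np.zeros(3)
        keep = reject(stats, obs, 0.1)
        perm = rng.permutation(400)
        keep_p = reject(stats[perm], obs, 0.1)
        assert set(perm[keep_p]) == set(keep)


class TestGLMAdjust:
    def test_zero_slope_recovers_retained_histogram(self, rng):
        # parameters independent of statistics: the adjusted posterior is
        # just a smoothed histogram of the retained draws
        theta = rng.normal(5.0, 1.0, 600)
        stats = rng.normal(0, 1, (600, 3))
        post = glm_adjust(stats, theta, np.zeros(3), prior_bounds=[(0.0, 10.0)])
        assert post.mean[0] == pytest.approx(theta.mean(), abs=0.15)
        assert post.mode[0] == pytest.approx(5.0, abs=0.5)

    def test_conjugate_linear_gaussian(self, rng):
        # theta ~ N(0,1), s = theta + N(0, sigma2): posterior mean is
        # s_obs / (1 + sigma2)
        sigma = 0.5
        theta = rng.normal(0, 1, 2000)
        s = theta + rng.normal(0, sigma, 2000)
        s_obs = 1.3
        post = glm_adjust(
            s[:, None], theta, np.array([s_obs]), prior_bounds=[(-6.0, 6.0)]
        )
        analytic = s_obs / (1 + sigma**2)
        assert post.mean[0] == pytest.approx(analytic, rel=0.05)

    def test_mass_confined_to_prior(self, rng):
        theta = rng.normal(0.0, 2.0, 500)
        stats = rng.normal(0, 1, (500, 2))
        post = glm_adjust(stats, theta, np.zeros(2), prior_bounds=[(0.0, 1.0)])
        assert 0.0 <= post.hdi_low[0] <= post.hdi_high[0] <= 1.0
        dx = post.grid[0, 1] - post.grid[0, 0]
        assert post.density[0].sum() * dx == pytest.approx(1.0)

    def test_mode_within_hdi(self, rng):
        theta = rng.normal(0.3, 0.05, 300)
        stats = rng.normal(0, 1, (300, 2))
        post = glm_adjust(stats, theta, np.zeros(2), prior_bounds=[(0.0, 1.0)])
        assert post.hdi_low[0] <= post.mode[0] <= post.hdi_high[0]

    def test_min_rows_guard(self, rng):
        with pytest.raises(ValueError):
            glm_adjust(rng.normal(0, 1, (50, 2)), rng.normal(0, 1, 50), np.zeros(2))


class TestHDI:
    def test_gaussian_interval(self):
        g = np.linspace(-6, 6, 2001)
        d = sps.norm.pdf(g)
        lo, hi = _hdi_from_grid(g, d, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_interval_mass(self):
        g = np.linspace(0, 1, 1000)
        d = sps.beta.pdf(g, 2, 5)
        lo, hi = _hdi_from_grid(g, d, 0.95)
        mass = sps.beta.cdf(hi, 2, 5) - sps.beta.cdf(lo, 2, 5)
        assert mass == pytest.approx(0.95, abs=0.01)


class TestMarginalDensityPValue:
    def test_center_vs_far(self, rng):
        X = rng.normal(0, 1, (800, 4))
        assert marginal_density_pvalue(X, np.zeros(4)) > 0.9
        assert marginal_density_pvalue(X, np.full(4, 8.0)) < 0.01

    def test_null_uniformity(self, rng):
        pvals = []
        for _ in range(200):
            X = rng.normal(0, 1, (300, 3))
            obs = rng.normal(0, 1, 3)
            pvals.append(marginal_density_pvalue(X, obs))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestModelChoice:
    def test_separable_scenarios(self, rng):
        a = rng.normal(0, 1, (300, 5))
        b = rng.normal(8, 1, (300, 5))
        res = rf_model_choice({"A": a, "B": b}, np.full(5, 8.0), n_trees=300)
        assert res.selected == "B"
        assert res.posterior_probability > 0.9
        assert np.allclose(np.diag(res.confusion_matrix), 1.0, atol=0.02)
        assert sum(res.votes.values()) == 300

    def test_identical_scenarios_are_random(self, rng):
        a = rng.normal(0, 1, (400, 5))
        b = rng.normal(0, 1, (400, 5))
        res = rf_model_choice({"A": a, "B": b}, np.zeros(5), n_trees=300)
        off = res.confusion_matrix[0, 1]
        assert off == pytest.approx(0.5, abs=0.15)

    def test_rows_sum_to_one(self, rng):
        a = rng.normal(0, 1, (200, 4))
        b = rng.normal(1, 1, (200, 4))
        res = rf_model_choice({"A": a, "B": b}, np.zeros(4), n_trees=200)
        assert np.allclose(res.confusion_matrix.sum(axis=1), 1.0)

    def test_more_trees_do_not_hurt(self, rng):
        # the stopping rationale for the forest size: beyond a few hundred
        # trees the out-of-bag error has flattened
        X1 = np.vstack([rng.normal(0, 1, (250, 4)), rng.normal(1.5, 1, (250, 4))])
        y = np.array(["A"] * 250 + ["B"] * 250)
        small = ScenarioChoiceForest(n_trees=300, random_state=0).fit(X1, y)
        big = ScenarioChoiceForest(n_trees=1000, random_state=0).fit(X1, y)
        assert big.oob_error_ <= small.oob_error_ + 0.03

    def test_single_scenario_rejected(self, rng):
        with pytest.raises(ValueError):
            rf_model_choice({"A": rng.normal(0, 1, (50, 3))}, np.zeros(3))


class TestRelativeBias:
    def test_perfect_estimator_is_unbiased(self, rng):
        # statistics identify the parameter exactly; the GLM adjustment
        # collapses every pseudo-observation onto its truth
        theta = rng.uniform(1.0, 2.0, 150)
        stats = theta[:, None]
        bias = relative_bias(
            stats, theta, estimator="mean", prior_bounds=[(0.5, 2.5)],
            max_pseudo=30, rng=rng,
        )
        assert bias[0] < 0.02

    def test_formula_on_known_ratios(self):
        # mu/chi ratios of 0.5 and 2 give mean |mu - chi| / chi = 0.75;
        # a doubled estimate gives exactly 1
        chis = np.array([1.0, 1.0])
        mus = np.array([0.5, 2.0])
        vals = np.abs(mus - chis) / chis
        assert vals.mean() == pytest.approx(0.75)
        assert np.abs(2 * chis - chis).mean() / 1.0 == pytest.approx(1.0)

    def test_zero_truth_excluded_with_warning(self, rng):
        theta = rng.uniform(1.0, 2.0, 120)
        theta[5] = 0.0
        stats = theta[:, None] + rng.normal(0, 0.01, (120, 1))
        with pytest.warns(UserWarning):
            relative_bias(
                stats, theta, prior_bounds=[(-0.5, 2.5)], max_pseudo=120, rng=rng
            )


class TestJointPosterior:
    def test_symmetric_probability_half(self, rng):
        theta = rng.normal(0, 1, (800, 2))  # exchangeable pair
        stats = rng.normal(0, 1, (800, 3))
        post = joint_posterior_2d(
            stats, theta, np.zeros(3), [(-5, 5), (-5, 5)], rng=1,
            n_draws=2000, burn_in=500,
        )
        p = prob_query(post, lambda x, y: x > y)
        assert p == pytest.approx(0.5, abs=0.06)
        assert np.all(post.rhat < 1.1)

    def test_point_mass_ratio_query(self, rng):
        x = rng.uniform(1.0, 1.2, 400)
        theta = np.column_stack([x, 5.0 * x])  # ratio exactly 5
        stats = rng.normal(0, 1, (400, 2))
        post = joint_posterior_2d(
            stats, theta, np.zeros(2), [(0.5, 2.0), (2.0, 10.0)], rng=2,
            n_draws=1500, burn_in=400,
        )
        p = prob_query(post, lambda x, y: (y / x >= 3) & (y / x <= 7))
        assert p > 0.99

    def test_gaussian_band_mass(self, rng):
        theta = rng.multivariate_normal([0, 0], [[1, 0], [0, 1]], 4000)
        stats = rng.normal(0, 1, (4000, 2))
        post = joint_posterior_2d(
            stats, theta, np.zeros(2), [(-6, 6), (-6, 6)], rng=3,
            n_draws=4000, burn_in=800,
        )
        p = prob_query(post, lambda x, y: np.abs(x) <= 1.0)
        analytic = sps.norm.cdf(1) - sps.norm.cdf(-1)
        assert p == pytest.approx(analytic, abs=0.03)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        est = PosteriorGLM(grid_size=500)
        params = est.get_params()
        assert params["grid_size"] == 500
        est2 = PosteriorGLM().set_params(**params)
        assert est2.grid_size == 500

    def test_forest_sklearn_clone(self):
        from sklearn.base import clone

        f = ScenarioChoiceForest(n_trees=123, random_state=9)
        g = clone(f)
        assert g.n_trees == 123 and g.random_state == 9
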