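"""Bayesian model: densities against independent oracles, sampler
behavior in the prior- and likelihood-dominated limits, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from ndfa import (
    BalanceDataset,
    BayesConfig,
    BetaParams,
    GammaParams,
    PosteriorSamples,
    ValidationError,
    assemble_priors,
    beta_moments,
    gelman_rubin,
    ols_fit,
    posterior_hyperparams,
    sample_posterior,
    scenario_preset,
    simulate_balance_dataset,
    summarize,
    theta_credible_estimate,
    theta_point,
)
from ndfa.bayes import (
    _split_rhat,
    log_likelihood,
    log_posterior,
    log_prior,
)


def make_samples(theta, beta1=None, sigma=None, config=None):
    theta = np.atleast_2d(theta)
    if beta1 is None:
        beta1 = np.ones_like(theta)
    if sigma is None:
        sigma = np.ones_like(theta)
    return PosteriorSamples(
        theta=theta, beta1=np.atleast_2d(beta1), sigma=np.atleast_2d(sigma),
        config=config or BayesConfig(seed=0),
    )


class TestLogLikelihood:
    def test_exact_line_reduces_to_normalizer(self):
        x = np.linspace(10, 90, 8)
        theta, beta1 = 0.5, 2.0
        ds = BalanceDataset(x=x, y=beta1 * (x - 100 * theta), balance_kind="pnb")
        assert log_likelihood(theta, beta1, 1.0, ds) == pytest.approx(
            -0.5 * ds.n * math.log(2 * math.pi)
        )

    def test_single_zero_residual_point(self):
        ds = BalanceDataset(x=[50.0], y=[0.0], balance_kind="pnb")
        assert log_likelihood(0.5, 2.0, 1.0, ds) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_matches_scipy_normal_density_sum(self):
        rng = np.random.default_rng(1)
        ds = BalanceDataset(
            x=rng.uniform(5, 95, 12), y=rng.normal(0, 40, 12), balance_kind="pnb"
        )
        theta, beta1, sigma = 0.62, 1.7, 23.0
        expected = stats.norm.logpdf(
            ds.y, loc=beta1 * (ds.x - 100 * theta), scale=sigma
        ).sum()
        assert log_likelihood(theta, beta1, sigma, ds) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(-0.1, 1, 1), (1.2, 1, 1), (0.5, -1, 1), (0.5, 1, 0)])
    def test_out_of_support_is_minus_inf(self, bad, empty_dataset):
        assert log_likelihood(*bad, empty_dataset) == -math.inf


class TestLogPrior:
    def test_matches_scipy_densities(self, field_pea_priors):
        theta, beta1, sigma = 0.55, 1.8, 30.0
        tp = field_pea_priors.theta_prior
        expected = (
            stats.beta.logpdf(theta, tp.alpha, tp.beta)
            + stats.gamma.logpdf(beta1, 1.6, scale=1 / 0.8)
            + stats.gamma.logpdf(sigma, 2.5, scale=1 / 0.05)
        )
        assert log_prior(theta, beta1, sigma, field_pea_priors) == pytest.approx(expected)

    def test_flat_theta_prior_contributes_zero(self):
        ps = assemble_priors(BetaParams(1, 1))
        for theta in (0.1, 0.5, 0.9):
            base = log_prior(theta, 2.0, 30.0, ps)
            assert base == pytest.approx(
                stats.gamma.logpdf(2.0, 1.6, scale=1 / 0.8)
                + stats.gamma.logpdf(30.0, 2.5, scale=1 / 0.05)
            )

    def test_sigma_prior_maximized_at_gamma_mode(self, field_pea_priors):
        # gamma(2.5, 0.05) has mode (shape-1)/rate = 30
        at_mode = log_prior(0.5, 2.0, 30.0, field_pea_priors)
        for sigma in (10.0, 29.0, 31.0, 80.0):
            assert log_prior(0.5, 2.0, sigma, field_pea_priors) <= at_mode

    def test_outside_support(self, field_pea_priors):
        assert log_prior(1.2, 2.0, 30.0, field_pea_priors) == -math.inf


class TestLogPosterior:
    def test_empty_data_equals_prior(self, field_pea_priors, empty_dataset):
        assert log_posterior(0.6, 2.0, 25.0, empty_dataset, field_pea_priors) == (
            log_prior(0.6, 2.0, 25.0, field_pea_priors)
        )

    def test_mode_near_ols_under_weak_priors(self, scenario_a_data):
        """With a flat theta prior and diffuse gamma priors, the posterior
        maximizer sits near the OLS solution."""
        from scipy.optimize import minimize

        weak = assemble_priors(
            BetaParams(1, 1),
            beta1=GammaParams(1.01, 0.01),
            sigma=GammaParams(1.01, 0.01),
        )
        fit = ols_fit(scenario_a_data)
        theta_ols = theta_point(fit) / 100.0

        def neg(z):
            return -log_posterior(z[0], z[1], z[2], scenario_a_data, weak)

        res = minimize(
            neg, x0=[0.5, 1.0, 20.0],
            bounds=[(1e-3, 1 - 1e-3), (1e-3, 10), (1.0, 200)],
        )
        assert res.x[0] == pytest.approx(theta_ols, abs=0.01)
        assert res.x[1] == pytest.approx(fit.beta1, abs=0.05)

    def test_finite_iff_in_support(self, field_pea_priors, empty_dataset):
        assert math.isfinite(log_posterior(0.5, 2.0, 25.0, empty_dataset, field_pea_priors))
        assert log_posterior(0.5, 0.0, 25.0, empty_dataset, field_pea_priors) == -math.inf


class TestSampler:
    def test_prior_recovery_with_no_data(self, field_pea_priors, empty_dataset, quick_config):
        samples = sample_posterior(empty_dataset, field_pea_priors, quick_config)
        prior_m = beta_moments(field_pea_priors.theta_prior)
        d = samples.pooled("theta")
        se = d.std(ddof=1) / np.sqrt(samples.convergence.ess["theta"])
        assert abs(d.mean() - prior_m.mean) < 3 * se

    def test_parameter_recovery_on_wide_range_data(self, field_pea_priors):
        cfg = scenario_preset("A", seed=21)
        import dataclasses

        cfg = dataclasses.replace(cfg, n=200)
        ds = simulate_balance_dataset(cfg)
        samples = sample_posterior(ds, field_pea_priors, BayesConfig(seed=21))
        assert 0.55 < samples.pooled("theta").mean() < 0.65

    def test_seeded_determinism(self, field_pea_priors, scenario_a_data, quick_config):
        a = sample_posterior(scenario_a_data, field_pea_priors, quick_config)
        b = sample_posterior(scenario_a_data, field_pea_priors, quick_config)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.beta1, b.beta1)
        assert np.array_equal(a.sigma, b.sigma)

    def test_boundary_regime_credible_interval_stays_viable(
        self, white_lupin_priors, quick_config
    ):
        ds = simulate_balance_dataset(scenario_preset("B", seed=13))
        samples = sample_posterior(ds, white_lupin_priors, quick_config)
        est = theta_credible_estimate(samples)
        assert 0.0 < est.ci_low < est.ci_high < 100.0
        assert est.nonviable_fraction == 0.0

    def test_draws_respect_supports(self, white_lupin_priors, quick_config):
        ds = simulate_balance_dataset(scenario_preset("B", seed=2))
        s = sample_posterior(ds, white_lupin_priors, quick_config)
        assert np.all((s.theta > 0) & (s.theta < 1))
        assert np.all(s.beta1 > 0) and np.all(s.sigma > 0)


class TestGelmanRubin:
    def test_identical_copies_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.beta(5, 5, size=20_000)
        samples = make_samples(np.tile(chain, (4, 1)))
        report = gelman_rubin(samples)
        assert report.rhat["theta"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_modes_flagged(self):
        a = np.full(500, 1.0) + np.random.default_rng(1).normal(0, 0.1, 500)
        b = np.full(500, 10.0) + np.random.default_rng(2).normal(0, 0.1, 500)
        assert _split_rhat(np.vstack([a, b])) > 1.5

    def test_well_mixed_iid_below_1_01(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((4, 10_000))
        assert _split_rhat(arr) < 1.01

    def test_agrees_with_arviz_on_iid_chains(self):
        import arviz as az

        rng = np.random.default_rng(4)
        arr = rng.standard_normal((4, 5_000))
        assert _split_rhat(arr) == pytest.approx(float(az.rhat(arr)), abs=0.005)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError):
            gelman_rubin(make_samples(np.full((1, 100), 0.5)))


class TestSummaries:
    def test_summarize_known_draws(self):
        rng = np.random.default_rng(8)
        draws = rng.beta(2, 2, size=(4, 5000))
        df = summarize(make_samples(draws))
        assert df.loc["theta", "mean"] == pytest.approx(0.5, abs=0.01)
        assert (
            df.loc["theta", "q2.5"]
            <= df.loc["theta", "median"]
            <= df.loc["theta", "q97.5"]
        )

    def test_constant_draws_zero_variance(self):
        df = summarize(make_samples(np.full((2, 100), 0.4)))
        assert df.loc["theta", "variance"] == 0.0

    def test_posterior_hyperparams_round_trip(self):
        rng = np.random.default_rng(9)
        theta = rng.beta(147.77, 24.26, size=(4, 50_000))
        beta1 = rng.gamma(35.0, 1 / 50.0, size=(4, 50_000))
        sigma = rng.gamma(25.82, 1 / 0.45, size=(4, 50_000))
        hp = posterior_hyperparams(make_samples(theta, beta1=beta1, sigma=sigma))
        assert hp["theta"].alpha == pytest.approx(147.77, rel=0.05)
        assert hp["beta1"].shape == pytest.approx(35.0, rel=0.05)
        assert hp["sigma"].shape == pytest.approx(25.82, rel=0.05)
        assert hp["sigma"].rate == pytest.approx(0.45, rel=0.05)

    def test_degenerate_draws_rejected(self):
        from ndfa import DomainError

        with pytest.raises(DomainError):
            posterior_hyperparams(make_samples(np.full((2, 100), 0.4)))


def test_prior_dominance_ordering(field_pea_priors, quick_config):
    """The theta marginal drifts from the prior toward the data as n grows."""
    import dataclasses

    prior_mean = beta_moments(field_pea_priors.theta_prior).mean
    cfg_small = dataclasses.replace(scenario_preset("A", seed=31), n=3)
    cfg_large = scenario_preset("A", seed=31)  # n = 100, truth 0.60
    means = {}
    for label, cfg in (("small", cfg_small), ("large", cfg_large)):
        ds = simulate_balance_dataset(cfg)
        means[label] = sample_posterior(ds, field_pea_priors, quick_config).pooled("theta").mean()
    # with almost no data the posterior hugs the prior more than with n=100
    assert abs(means["small"] - prior_mean) < abs(prior_mean - 0.60) + 0.05
    assert abs(means["large"] - 0.60) < abs(means["small"] - 0.60) + 0.02


def test_likelihood_dominance_matches_ols(quick_config):
    """With a flat theta prior and plenty of data the posterior mean of
    100*theta lands within a percentage point of the OLS x-intercept."""
    ds = simulate_balance_dataset(scenario_preset("A", seed=17))
    weak = assemble_priors(BetaParams(1, 1))
    samples = sample_posterior(ds, weak, quick_config)
    theta_ols = theta_point(ols_fit(ds))
    assert 100 * samples.pooled("theta").mean() == pytest.approx(theta_ols, abs=1.0)
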