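"""Tests of the posterior machinery: prior recovery, oracle agreement,
functional identities and parameter recovery."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from blrm2 import (
    PriorHyperparameters,
    SamplerSettings,
    ThetaVector,
    TrialData,
    combination_risk,
    grid_posterior_oracle,
    log_likelihood,
    log_prior,
    prob_exceeds,
    prob_in_interval,
    sample_posterior,
)


class TestLogPrior:
    def test_maximal_at_prior_centre(self, hyper):
        x0 = np.array(
            [hyper.mu0[0], hyper.log_slope_mean[0], hyper.mu0[1], hyper.log_slope_mean[1], 0.0]
        )
        lp_centre = log_prior(x0, hyper, slope_space=False)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = x0 + rng.normal(scale=0.5, size=5)
            if hyper.eta_nonnegative:
                x[4] = abs(x[4])
            assert log_prior(x, hyper, slope_space=False) <= lp_centre + 1e-9

    def test_matches_independent_gaussian_evaluation(self, hyper):
        # frozen cross-check against scipy multivariate_normal
        from scipy.stats import multivariate_normal

        x = np.array([-3.2, 0.1, -2.9, -0.4, 0.7])
        lp = log_prior(x, hyper, slope_space=False)
        expected = 0.0
        for agent, (a, l) in enumerate(((x[0], x[1]), (x[2], x[3]))):
            mv = multivariate_normal(
                [hyper.mu0[agent], hyper.log_slope_mean[agent]], hyper.covariance(agent)
            )
            expected += mv.logpdf([a, l])
        if hyper.eta_nonnegative:
            expected += norm.logpdf(x[4], 0, hyper.sigma_eta) + np.log(2)
        else:
            expected += norm.logpdf(x[4], 0, hyper.sigma_eta)
        assert lp == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_slope_has_zero_density(self, hyper):
        theta = np.array([-3.75, -0.1, -3.25, 0.5, 0.0])
        assert log_prior(theta, hyper, slope_space=True) == -np.inf

    def test_covariance_enters_through_cross_term(self):
        base = PriorHyperparameters()
        tilted = PriorHyperparameters(sigma01=(0.05, 0.0))
        x = np.array([-3.75, 0.40, -3.25, 0.05, 0.0])  # centred: no cross term
        assert log_prior(x, base, slope_space=False) != pytest.approx(
            log_prior(x, tilted, slope_space=False)
        )  # normalising constant differs
        d_base = log_prior(x + np.array([0.3, 0.3, 0, 0, 0]), base, slope_space=False) - log_prior(x, base, slope_space=False)
        d_tilt = log_prior(x + np.array([0.3, 0.3, 0, 0, 0]), tilted, slope_space=False) - log_prior(x, tilted, slope_space=False)
        assert d_tilt > d_base  # positive covariance rewards joint displacement


class TestLogLikelihood:
    def test_empty_data_is_zero(self, hyper):
        theta = ThetaVector(-3.75, 0.4, -3.25, 0.05, 0.2).as_array()
        assert log_likelihood(theta, TrialData()) == 0.0

    def test_half_risk_record_gives_log_half(self, refs):
        # pick theta so that risk(60, 30) = 0.5 exactly via the intercepts
        theta = np.array([np.log(1.0), 0.4, -30.0, 0.05, 0.0])
        # p_m = expit(0) = 0.5, p_b ~ 0 -> combination = 0.5
        data = TrialData.from_records([(60, 30, 1)])
        assert log_likelihood(theta, data, refs) == pytest.approx(np.log(0.5), abs=1e-6)
        data0 = TrialData.from_records([(60, 30, 0)])
        assert log_likelihood(theta, data0, refs) == pytest.approx(np.log(0.5), abs=1e-6)

    def test_dlt_record_value(self, refs):
        # hand-computed Bernoulli kernel at a fixed theta for one DLT record
        theta = ThetaVector(-3.75, 0.40, -3.25, 0.05, 1.0)
        p = float(combination_risk(theta, 58, 90, refs))
        data = TrialData.from_records([(58, 90, 1)])
        assert log_likelihood(theta.as_array(), data, refs) == pytest.approx(
            np.log(p), rel=1e-12
        )


class TestPriorRecovery:
    def test_empty_data_reproduces_prior_moments(self, hyper, fast_settings):
        draws = sample_posterior(hyper, TrialData(), fast_settings, seed=5)
        arr = draws.draws
        n_eff = 2000  # conservative effective size for the error bars
        # intercepts
        for idx, (mu, sd) in [(0, (hyper.mu0[0], hyper.sigma0[0])),
                              (2, (hyper.mu0[1], hyper.sigma0[1]))]:
            assert abs(arr[:, idx].mean() - mu) < 3 * sd / np.sqrt(n_eff) + 0.05
        # log-slopes
        for idx, (mu, sd) in [(1, (hyper.log_slope_mean[0], hyper.sigma1[0])),
                              (3, (hyper.log_slope_mean[1], hyper.sigma1[1]))]:
            assert abs(np.log(arr[:, idx]).mean() - mu) < 3 * sd / np.sqrt(n_eff) + 0.05
        # interaction: half-normal or normal moments
        eta = arr[:, 4]
        if hyper.eta_nonnegative:
            expected = hyper.sigma_eta * np.sqrt(2 / np.pi)
            assert np.all(eta >= 0)
        else:
            expected = 0.0
        assert abs(eta.mean() - expected) < 0.1

    def test_dlts_raise_posterior_risk(self, hyper, fast_settings, config):
        clean = TrialData.from_records([(50, 30, 0)] * 6)
        toxic = TrialData.from_records([(50, 30, 1)] * 6)
        d_clean = sample_posterior(hyper, clean, fast_settings, seed=1)
        d_toxic = sample_posterior(hyper, toxic, fast_settings, seed=1)
        m, b = config.safety_check_combo
        assert np.mean(d_toxic.risk(m, b)) > np.mean(d_clean.risk(m, b))


class TestFunctionalIdentities:
    def test_interval_probability_identity(self, hyper, fast_settings):
        data = TrialData.from_records([(40, 10, 0), (60, 30, 1), (80, 30, 0)])
        draws = sample_posterior(hyper, data, fast_settings, seed=9)
        lo, hi = 0.15, 0.25
        lhs = prob_in_interval(draws, 100, 60, lo, hi)
        rhs = prob_exceeds(draws, 100, 60, lo) - prob_exceeds(draws, 100, 60, hi)
        # differs only by draws exactly at the band edges (measure zero)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_degenerate_bounds(self, hyper, fast_settings):
        draws = sample_posterior(hyper, TrialData(), fast_settings, seed=2)
        assert prob_in_interval(draws, 60, 30, 0.0, 1.0) == 1.0
        assert prob_exceeds(draws, 60, 30, 1.0) == 0.0
        with pytest.raises(ValueError):
            prob_in_interval(draws, 60, 30, 0.3, 0.2)


class TestGridOracle:
    def test_empty_data_matches_prior_monte_carlo(self, hyper):
        # prior mean risk from the quadrature vs a large direct Monte Carlo
        oracle = grid_posterior_oracle(hyper, TrialData(), n_nodes=13)
        rng = np.random.default_rng(77)
        n = 200_000
        a01 = rng.normal(hyper.mu0[0], hyper.sigma0[0], n)
        a02 = rng.normal(hyper.mu0[1], hyper.sigma0[1], n)
        s1 = np.exp(rng.normal(hyper.log_slope_mean[0], hyper.sigma1[0], n))
        s2 = np.exp(rng.normal(hyper.log_slope_mean[1], hyper.sigma1[1], n))
        eta = rng.normal(0, hyper.sigma_eta, n)
        if hyper.eta_nonnegative:
            eta = np.abs(eta)
        theta = np.stack([a01, s1, a02, s2, eta], axis=-1)
        mc = float(np.mean(combination_risk(theta, 60, 30, hyper.refs)))
        assert oracle.mean_risk(60, 30) == pytest.approx(mc, abs=0.01)

    def test_sampler_agrees_with_oracle_on_small_datasets(self, hyper, config):
        rng = np.random.default_rng(13)
        settings = SamplerSettings(n_walkers=64, n_steps=3000, n_burn=1000)
        worst = 0.0
        for i in range(5):
            n = int(rng.integers(3, 10))
            recs = [
                (
                    float(rng.integers(10, 151)),
                    float(rng.choice(config.b_doses)),
                    int(rng.random() < 0.25),
                )
                for _ in range(n)
            ]
            data = TrialData.from_records(recs)
            draws = sample_posterior(hyper, data, settings, seed=100 + i)
            oracle = grid_posterior_oracle(hyper, data, n_nodes=15)
            for m, b in [config.high_combo, config.safety_check_combo, (90.0, 60.0)]:
                d = abs(
                    prob_exceeds(draws, m, b, config.target_hi)
                    - oracle.prob_exceeds(m, b, config.target_hi)
                )
                worst = max(worst, d)
        assert worst < 0.02

    def test_oversized_grid_rejected(self, hyper):
        with pytest.raises(ValueError):
            grid_posterior_oracle(hyper, TrialData(), n_nodes=30)


class TestParameterRecovery:
    def test_credible_interval_coverage_at_safety_check(self, hyper, config):
        """90% posterior intervals for risk(60,30) cover the truth >= 85%.

        Each replicate simulates 200 patients over spread-out dose pairs
        from a known parameter vector drawn from the prior, so the nominal
        coverage of the credible interval is exact in expectation and the
        check exercises likelihood, sampler and interval construction
        together.
        """
        rng = np.random.default_rng(404)
        settings = SamplerSettings(n_walkers=30, n_steps=500, n_burn=200)
        n_rep, covered = 50, 0
        for rep in range(n_rep):
            truth = ThetaVector(
                rng.normal(hyper.mu0[0], hyper.sigma0[0]),
                float(np.exp(rng.normal(hyper.log_slope_mean[0], hyper.sigma1[0]))),
                rng.normal(hyper.mu0[1], hyper.sigma0[1]),
                float(np.exp(rng.normal(hyper.log_slope_mean[1], hyper.sigma1[1]))),
                abs(rng.normal(0, hyper.sigma_eta))
                if hyper.eta_nonnegative
                else rng.normal(0, hyper.sigma_eta),
            )
            true_risk = float(combination_risk(truth, 60, 30))
            m = rng.integers(10, 151, size=200).astype(float)
            b = rng.choice(config.b_doses, size=200)
            p = combination_risk(truth, m, b)
            y = (rng.random(200) < p).astype(int)
            data = TrialData.from_records(list(zip(m, b, y)))
            draws = sample_posterior(hyper, data, settings, seed=500 + rep)
            lo, hi = np.quantile(draws.risk(60, 30), [0.05, 0.95])
            covered += lo <= true_risk <= hi
        assert covered / n_rep >= 0.85
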