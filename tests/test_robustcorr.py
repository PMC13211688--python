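"""Bivariate-t log posterior (against an independent density oracle), HDI,
convergence diagnostics, and posterior recovery of the robust correlation."""

import math

import numpy as np
import pytest
from scipy import stats

from ecotransfer.robustcorr import (
    DegenerateDataError,
    McmcSettings,
    RobustCorrPriors,
    RobustCorrelation,
    ess,
    hdi,
    log_posterior,
    rhat,
    sample_posterior,
)
from ecotransfer.simulate import generate_bivariate_t


def _manual_log_prior(mu1, mu2, s1, s2, nu, priors):
    lp = 0.0
    for mu, loc, scale in zip((mu1, mu2), priors.mu_loc, priors.mu_scale):
        lp += stats.norm.logpdf(mu, loc, scale)
    for s, scale in zip((s1, s2), priors.sigma_scale):
        lp += stats.halfnorm.logpdf(s, scale=scale)
    lp += math.log(0.5)  # Uniform(-1, 1)
    lp += stats.expon.logpdf(nu - 1.0, scale=priors.nu_minus_one_mean)
    return lp


class TestLogPosterior:
    def _data(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        return rng.normal(0, 1, n), rng.normal(0, 2, n)

    @pytest.mark.parametrize("rho,nu", [(0.0, 4.0), (0.6, 7.5), (-0.8, 30.0)])
    def test_matches_multivariate_t_oracle(self, rho, nu):
        x, y = self._data()
        priors = RobustCorrPriors.from_data(x, y)
        params = {"mu1": 0.2, "mu2": -0.1, "sigma1": 1.1, "sigma2": 1.8, "rho": rho, "nu": nu}
        cov = np.array(
            [
                [params["sigma1"] ** 2, rho * params["sigma1"] * params["sigma2"]],
                [rho * params["sigma1"] * params["sigma2"], params["sigma2"] ** 2],
            ]
        )
        oracle = stats.multivariate_t(
            loc=[params["mu1"], params["mu2"]], shape=cov, df=nu
        ).logpdf(np.column_stack([x, y])).sum()
        oracle += _manual_log_prior(
            params["mu1"], params["mu2"], params["sigma1"], params["sigma2"], nu, priors
        )
        assert log_posterior(params, x, y, priors) == pytest.approx(oracle, abs=1e-9)

    def test_single_observation_at_mode(self):
        # at the location, the bivariate-t density reduces to its normalising
        # constant: Gamma((nu+2)/2) / (Gamma(nu/2) nu pi |Sigma|^1/2)
        x, y = np.array([1.0, 0.0, 2.0]), np.array([1.0, 0.5, 1.5])
        priors = RobustCorrPriors.from_data(x, y)
        nu = 5.0
        single = stats.multivariate_t(loc=[1.0, 1.0], shape=np.eye(2), df=nu).logpdf([1.0, 1.0])
        expected = (
            math.lgamma((nu + 2) / 2) - math.lgamma(nu / 2) - math.log(nu * math.pi)
        )
        assert single == pytest.approx(expected, abs=1e-12)

    def test_large_nu_approaches_bivariate_normal(self):
        x, y = self._data(seed=3, n=20)
        priors = RobustCorrPriors.from_data(x, y)
        params = {"mu1": 0.0, "mu2": 0.0, "sigma1": 1.0, "sigma2": 2.0, "rho": 0.5, "nu": 1e6}
        cov = np.array([[1.0, 0.5 * 2.0], [0.5 * 2.0, 4.0]])
        normal_ll = stats.multivariate_normal(mean=[0, 0], cov=cov).logpdf(
            np.column_stack([x, y])
        ).sum()
        got_ll = log_posterior(params, x, y, priors) - _manual_log_prior(
            0.0, 0.0, 1.0, 2.0, 1e6, priors
        )
        assert got_ll == pytest.approx(normal_ll, abs=1e-3)

    @pytest.mark.parametrize(
        "bad", [{"rho": 1.0}, {"rho": -1.5}, {"sigma1": 0.0}, {"nu": 1.0}]
    )
    def test_invalid_parameters_give_minus_inf(self, bad):
        x, y = self._data()
        priors = RobustCorrPriors.from_data(x, y)
        params = {"mu1": 0.0, "mu2": 0.0, "sigma1": 1.0, "sigma2": 1.0, "rho": 0.0, "nu": 5.0}
        params.update(bad)
        assert log_posterior(params, x, y, priors) == -np.inf


class TestHdi:
    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 3.25))
        assert lo == hi == 3.25

    def test_standard_normal_interval(self):
        draws = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_skewed_sample_hdi_shorter_than_equal_tailed(self):
        draws = np.random.default_rng(1).exponential(1.0, 50_000)
        lo, hi = hdi(draws, 0.95)
        q_lo, q_hi = np.quantile(draws, [0.025, 0.975])
        assert (hi - lo) < (q_hi - q_lo)


class TestDiagnostics:
    def test_rhat_of_iid_chains_is_small(self):
        chains = np.random.default_rng(2).standard_normal((4, 2000))
        assert rhat(chains) < 1.01

    def test_rhat_detects_mean_shifted_chain(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 2000))
        chains[0] += 5.0
        assert rhat(chains) > 1.1

    def test_rhat_of_copied_chains_not_inflated(self):
        chain = np.random.default_rng(4).standard_normal(1000)
        assert rhat(np.stack([chain, chain, chain])) <= 1.0 + 1e-6

    def test_ess_of_iid_draws_near_total(self):
        chains = np.random.default_rng(5).standard_normal((4, 2000))
        assert ess(chains) == pytest.approx(8000, rel=0.2)

    def test_ess_of_ar1_chain_matches_closed_form(self):
        rng = np.random.default_rng(6)
        phi, n = 0.9, 20_000
        chains = np.empty((2, n))
        for c in range(2):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = phi * x[t - 1] + e[t]
            chains[c] = x
        expected = 2 * n * (1 - phi) / (1 + phi)
        assert ess(chains) == pytest.approx(expected, rel=0.3)

    def test_ess_of_constant_chains_is_nan_sentinel(self):
        assert math.isnan(ess(np.ones((2, 500))))


FAST = dict(n_chains=4, n_draws=800, n_tune=500)


class TestSampling:
    def test_recovers_strong_positive_correlation(self):
        xy = generate_bivariate_t(200, 0.8, 5.0, seed=21)
        est = RobustCorrelation(seed=1, **FAST).fit(xy[:, 0], xy[:, 1])
        assert est.rho_mean_ == pytest.approx(0.8, abs=0.1)
        assert est.hdi_low_ <= 0.8 <= est.hdi_high_

    def test_null_correlation_hdi_contains_zero(self):
        xy = generate_bivariate_t(200, 0.0, 5.0, seed=22)
        est = RobustCorrelation(seed=2, **FAST).fit(xy[:, 0], xy[:, 1])
        assert est.hdi_low_ <= 0.0 <= est.hdi_high_

    def test_label_symmetry(self):
        xy = generate_bivariate_t(60, 0.6, 6.0, seed=23)
        a = RobustCorrelation(seed=3, **FAST).fit(xy[:, 0], xy[:, 1])
        b = RobustCorrelation(seed=3, **FAST).fit(xy[:, 1], xy[:, 0])
        assert a.rho_mean_ == pytest.approx(b.rho_mean_, abs=0.02)

    def test_sign_equivariance(self):
        xy = generate_bivariate_t(60, 0.6, 6.0, seed=24)
        a = RobustCorrelation(seed=4, **FAST).fit(xy[:, 0], xy[:, 1])
        b = RobustCorrelation(seed=4, **FAST).fit(xy[:, 0], -xy[:, 1])
        assert a.rho_mean_ == pytest.approx(-b.rho_mean_, abs=0.02)

    def test_outlier_downweighted_relative_to_pearson(self):
        # 6 tightly correlated pairs plus one gross discordant outlier
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0])
        y = np.array([1.1, 1.9, 3.2, 3.9, 5.1, 6.0, -10.0])
        r_clean = np.corrcoef(x[:-1], y[:-1])[0, 1]
        r_all = np.corrcoef(x, y)[0, 1]
        est = RobustCorrelation(seed=5, **FAST).fit(x, y)
        assert abs(est.rho_mean_ - r_clean) < abs(r_all - r_clean)

    def test_degenerate_data_rejected_before_sampling(self):
        with pytest.raises(DegenerateDataError):
            sample_posterior(np.ones(5), np.arange(5.0), McmcSettings(seed=0))

    def test_get_set_params_round_trip(self):
        est = RobustCorrelation()
        est.set_params(n_draws=123, seed=9)
        assert est.get_params()["n_draws"] == 123 and est.get_params()["seed"] == 9
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
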