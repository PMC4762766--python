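"""Left-truncated Weibull PH likelihood, MLE, and per-coefficient tests.

Oracles: a direct re-implementation of the likelihood from the distribution
functions, the exponential-model closed form, and lifelines' WeibullAFTFitter
(the AFT and PH parameterisations map onto each other for the Weibull).
"""

import math

import numpy as np
import pandas as pd
import pytest

from idpower.design import CohortDesign, EffectSpec, ExposureSpec, FrailtySpec, Scenario
from idpower.estimate import (
    DataError,
    PARAM_NAMES,
    UndefinedTestError,
    FitResult,
    fit_weibull_ph,
    likelihood_ratio_test,
    neg_log_likelihood,
    wald_test,
)
from idpower.simulate import simulate_dataset
from idpower.truncweibull import WeibullParams, weibull_cdf, weibull_pdf


def _recovery_scenario(n=30_000, beta_env=math.log(1.5)):
    return Scenario.from_preset(
        "diabetes",
        design=CohortDesign(n_subjects=n, visit_interval_years="continuous"),
        exposures=ExposureSpec(0.3, 0.3),
        effects=EffectSpec(beta_env=beta_env),
        frailty=FrailtySpec(sd=0.0),
    )


def _oracle_nll(params, records):
    """Independent likelihood evaluation from the distribution functions.

    Under proportional hazards the subject-specific scale is
    lam0 * exp(-eta/rho); events contribute the log truncated density and
    censored records the log conditional survival.
    """
    a, b, be, bg, bge = params
    lam0, rho = math.exp(a), math.exp(b)
    total = 0.0
    for row in records.itertuples():
        xe = getattr(row, "x_env_obs", None)
        xe = row.x_env if xe is None else xe
        xg = getattr(row, "x_gen_obs", None)
        xg = row.x_gen if xg is None else xg
        eta = be * xe + bg * xg + bge * xe * xg
        p = WeibullParams(lam0 * math.exp(-eta / rho), rho)
        surv_l = 1 - weibull_cdf(row.l, p)
        if row.event:
            total += math.log(weibull_pdf(row.t, p) / surv_l)
        else:
            total += math.log((1 - weibull_cdf(row.t, p)) / surv_l)
    return -total


class TestNegLogLikelihood:
    def test_empty_records(self):
        empty = pd.DataFrame(columns=["l", "t", "event", "x_env", "x_gen"])
        assert neg_log_likelihood(np.zeros(5), empty) == 0.0

    def test_matches_independent_oracle(self):
        scen = _recovery_scenario(n=200)
        data = simulate_dataset(scen, 7)
        params = [math.log(70.0), math.log(2.2), 0.3, -0.1, 0.2]
        assert neg_log_likelihood(params, data) == pytest.approx(
            _oracle_nll(params, data), rel=1e-10
        )

    def test_shifted_truncation_matches_oracle(self):
        # adding a constant to all entry and observation times changes the
        # likelihood exactly as direct re-evaluation says it should
        scen = _recovery_scenario(n=150)
        data = simulate_dataset(scen, 11)
        shifted = data.assign(l=data["l"] + 4.0, t=data["t"] + 4.0)
        params = [math.log(65.0), math.log(2.0), 0.0, 0.0, 0.0]
        assert neg_log_likelihood(params, shifted) == pytest.approx(
            _oracle_nll(params, shifted), rel=1e-10
        )

    def test_exponential_special_case_closed_form(self, rng):
        """With shape fixed at 1, no truncation/censoring/covariates, the
        scale MLE is total time / number of events."""
        t = rng.exponential(20.0, 500)
        data = pd.DataFrame(
            {"l": 0.0, "t": t, "event": 1, "x_env": 0, "x_gen": 0}
        )
        closed_form = math.log(t.sum() / len(t))
        grid = np.linspace(closed_form - 0.5, closed_form + 0.5, 2001)
        vals = [neg_log_likelihood([a, 0.0, 0, 0, 0], data) for a in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(closed_form, abs=1e-3)

    def test_records_at_truncation_rejected(self):
        data = pd.DataFrame({"l": [5.0], "t": [5.0], "event": [1], "x_env": [0], "x_gen": [0]})
        with pytest.raises(DataError):
            neg_log_likelihood(np.zeros(5), data)


class TestFit:
    def test_parameter_recovery_within_three_se(self):
        scen = _recovery_scenario()
        fit = fit_weibull_ph(simulate_dataset(scen, 2024))
        assert fit.converged
        err = abs(fit.estimate("beta_env") - math.log(1.5))
        assert err < 3 * fit.stderr("beta_env")
        # baseline parameters are also identified in the well-specified case;
        # calibration divides every hazard by c = E[exp(beta x)], so the
        # unexposed group's scale is preset * c^(1/shape)
        c = 0.7 + 0.3 * 1.5
        assert fit.estimate("log_scale") == pytest.approx(
            math.log(65.0) + math.log(c) / 2.0, abs=4 * fit.stderr("log_scale")
        )
        assert fit.estimate("log_shape") == pytest.approx(
            math.log(2.0), abs=4 * fit.stderr("log_shape")
        )

    def test_refit_is_bit_identical(self):
        data = simulate_dataset(_recovery_scenario(n=2_000), 5)
        f1 = fit_weibull_ph(data)
        f2 = fit_weibull_ph(data)
        np.testing.assert_array_equal(f1.params, f2.params)
        np.testing.assert_array_equal(f1.cov, f2.cov)

    def test_degenerate_design_flagged(self):
        scen = _recovery_scenario(n=2_000, beta_env=0.0).replace(
            exposures=ExposureSpec(0.0, 0.0)
        )
        fit = fit_weibull_ph(simulate_dataset(scen, 3))
        assert any(f.startswith("constant_covariate") for f in fit.flags)
        assert fit.estimate("beta_env") == 0.0
        assert np.isnan(fit.stderr("beta_env"))

    def test_covariance_is_symmetric_psd_on_free_block(self):
        fit = fit_weibull_ph(simulate_dataset(_recovery_scenario(n=5_000), 13))
        cov = fit.cov
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_zero_events_rejected(self):
        data = pd.DataFrame({"l": [0.0], "t": [1.0], "event": [0], "x_env": [0], "x_gen": [0]})
        with pytest.raises(DataError):
            fit_weibull_ph(data)

    def test_matches_lifelines_left_truncated_fit(self):
        """Cross-check against lifelines' Weibull AFT fit with late entry.

        The AFT coefficient on a covariate equals -beta_PH / shape, and the
        log likelihoods coincide at the optimum.
        """
        lifelines = pytest.importorskip("lifelines")
        data = simulate_dataset(_recovery_scenario(n=4_000), 99)
        fit = fit_weibull_ph(data)

        df = data.rename(columns={"x_env_obs": "xe", "x_gen_obs": "xg"})[
            ["l", "t", "event", "xe", "xg"]
        ].astype(float)
        df["xexg"] = df["xe"] * df["xg"]
        aft = lifelines.WeibullAFTFitter()
        aft.fit(df, duration_col="t", event_col="event", entry_col="l")
        rho = math.exp(fit.estimate("log_shape"))
        assert aft.params_[("lambda_", "xe")] == pytest.approx(
            -fit.estimate("beta_env") / rho, abs=2e-3
        )
        assert aft.params_[("lambda_", "Intercept")] == pytest.approx(
            fit.estimate("log_scale"), abs=2e-3
        )
        assert aft.log_likelihood_ == pytest.approx(fit.loglik, rel=1e-6)


class TestWaldTest:
    @staticmethod
    def _fit_with(estimate, se):
        params = np.zeros(5)
        params[2] = estimate
        cov = np.eye(5) * se**2
        return FitResult(
            params=params, cov=cov, loglik=0.0, converged=True, n_events=10, n_records=20
        )

    def test_null_estimate_never_rejects(self):
        res = wald_test(self._fit_with(0.0, 0.1), "beta_env", 0.05)
        assert res.p_value == 1.0
        assert not res.reject

    def test_boundary_z_does_not_reject(self):
        # strict inequality: |z| exactly at the critical value is not a rejection
        from scipy.stats import norm

        zc = norm.isf(0.025)
        res = wald_test(self._fit_with(zc * 0.1, 0.1), "beta_env", 0.05)
        assert res.p_value == pytest.approx(0.05, abs=1e-12)
        assert not res.reject

    def test_reject_flag_consistent_with_p(self):
        res = wald_test(self._fit_with(0.5, 0.1), "beta_env", 0.05)
        assert res.reject == (res.p_value < 0.05)
        assert res.reject

    def test_unconverged_fit_rejected(self):
        fit = self._fit_with(0.5, 0.1)
        fit.converged = False
        with pytest.raises(UndefinedTestError):
            wald_test(fit, "beta_env", 0.05)

    def test_zero_se_rejected(self):
        with pytest.raises(UndefinedTestError):
            wald_test(self._fit_with(0.5, 0.0), "beta_env", 0.05)

    def test_wald_and_lrt_decisions_agree(self):
        """Wald and likelihood-ratio decisions coincide in >= 99% of
        moderately powered replicates."""
        scen = _recovery_scenario(n=2_000, beta_env=math.log(1.6))
        agree = 0
        n_data = 60
        for r in range(n_data):
            data = simulate_dataset(scen, 10_000 + r)
            w = wald_test(fit_weibull_ph(data), "beta_env", 0.05)
            lr = likelihood_ratio_test(data, "beta_env", 0.05)
            agree += w.reject == lr.reject
        assert agree >= math.ceil(0.99 * n_data)


class TestCalibration:
    def test_wald_coverage_and_size_under_well_specified_model(self):
        """95% Wald intervals cover the true beta at ~95%, and the size of the
        test under the null is ~alpha (frailty-free continuous scenarios)."""
        beta = math.log(1.5)
        scen_alt = _recovery_scenario(n=2_000, beta_env=beta)
        scen_null = _recovery_scenario(n=2_000, beta_env=0.0)
        cover = reject = 0
        n_reps = 500
        for r in range(n_reps):
            fit = fit_weibull_ph(simulate_dataset(scen_alt, 20_000 + r))
            half = 1.959963984540054 * fit.stderr("beta_env")
            cover += abs(fit.estimate("beta_env") - beta) < half
            fit0 = fit_weibull_ph(simulate_dataset(scen_null, 50_000 + r))
            reject += wald_test(fit0, "beta_env", 0.05).reject
        # three binomial SEs around the nominal levels
        assert cover / n_reps == pytest.approx(0.95, abs=3 * math.sqrt(0.95 * 0.05 / n_reps))
        assert reject / n_reps == pytest.approx(0.05, abs=3 * math.sqrt(0.05 * 0.95 / n_reps))
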