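"""Interval-censored log-normal AFT: likelihood, quadrature, fitting,
covariances, effect transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import hipwait as hw
from hipwait.interval_model import (IntervalData, _obs_logp, build_interval,
                                    build_intervals, cluster_loglik,
                                    fit_interval_lognormal, modal_profile,
                                    observed_information, sandwich_vcov)


class TestIntervals:
    @pytest.mark.parametrize("n,expect", [
        (2, (1.0, 2.0, "interval")),
        (3, (2.0, 3.0, "interval")),
        (7, (6.0, 7.0, "interval")),
        (1, (0.0, 1.0, "left")),
        (8, (7.0, np.inf, "right")),
        (9, (7.0, np.inf, "right")),
    ])
    def test_day_to_interval(self, n, expect):
        assert build_interval(n) == expect

    def test_vectorised_log_bounds(self):
        lo, up = build_intervals([1, 2, 9])
        assert np.isneginf(lo[0]) and up[0] == 0.0          # log(0), log(1)
        assert lo[1] == pytest.approx(0.0) and up[1] == pytest.approx(np.log(2))
        assert lo[2] == pytest.approx(np.log(7)) and np.isposinf(up[2])

    def test_invalid_day(self):
        with pytest.raises(ValueError):
            build_interval(0)


def _data(lo, up, X=None, cluster=None, score=None, exact=None, names=None):
    n = len(lo)
    X = np.ones((n, 1)) if X is None else np.asarray(X, float)
    cluster = np.zeros(n, int) if cluster is None else cluster
    return IntervalData.from_arrays(lo, up, X, cluster, demand_score=score,
                                    is_exact=exact,
                                    names=names or [f"b{j}" for j in
                                                    range(X.shape[1])])


class TestLoglik:
    def test_total_probability_open_intervals(self):
        d = _data(np.full(4, -np.inf), np.full(4, np.inf), cluster=np.arange(4))
        assert hw.loglik([0.3, np.log(0.7)], d, random_effects="none") == 0.0

    def test_single_observation_two_phi_formula(self):
        d = _data([np.log(1)], [np.log(2)])
        got = hw.loglik([0.4, np.log(0.6)], d, random_effects="none")
        expect = np.log(norm.cdf((np.log(2) - 0.4) / 0.6)
                        - norm.cdf((np.log(1) - 0.4) / 0.6))
        assert got == pytest.approx(expect, abs=1e-10)

    def test_derivatives_match_numeric(self, rng):
        n = 60
        lo = rng.normal(size=n)
        up = lo + np.abs(rng.normal(size=n)) + 0.05
        lo[0], up[1] = -np.inf, np.inf
        exact = np.zeros(n, bool)
        exact[2] = True
        lo[2] = up[2] = 0.4
        d = _data(lo, up, exact=exact)
        eta = 0.4 * rng.normal(size=n)
        lp, d1, d2 = _obs_logp(eta, 0.7, d, derivs=True)
        h = 1e-5
        lp_p = _obs_logp(eta + h, 0.7, d)
        lp_m = _obs_logp(eta - h, 0.7, d)
        assert np.allclose((lp_p - lp_m) / (2 * h), d1, atol=1e-6)
        assert np.allclose((lp_p - 2 * lp + lp_m) / h ** 2, d2, atol=1e-3)

    def test_widening_interval_never_decreases_probability(self, rng):
        lo = np.array([0.0, 0.5, -0.3])
        up = np.array([0.7, 1.5, 0.4])
        d_narrow = _data(lo, up)
        d_wide = _data(lo - 0.3, up + 0.4)
        for eta0 in (-1.0, 0.0, 0.8):
            eta = np.full(3, eta0)
            assert np.all(_obs_logp(eta, 0.6, d_wide)
                          >= _obs_logp(eta, 0.6, d_narrow))

    def test_quadrature_against_numerical_integration(self):
        lo = np.array([0.0, 0.69])
        up = np.array([0.69, 1.1])
        d = _data(lo, up, cluster=[0, 0])
        beta0, sig, tau = 0.5, 0.6, 0.3

        def integrand(b):
            p = (norm.cdf((up - beta0 - b) / sig)
                 - norm.cdf((lo - beta0 - b) / sig)).prod()
            return p * norm.pdf(b, 0, tau)

        expect = np.log(quad(integrand, -10, 10, limit=200)[0])
        got = hw.loglik([beta0, np.log(sig), np.log(tau)], d, "intercept")
        assert got == pytest.approx(expect, abs=1e-9)

    def test_quadrature_node_count_converged(self, rng):
        """9 vs 15 adaptive nodes on a 5-hospital toy set."""
        n = 60
        nday = rng.integers(1, 9, n)
        lo, up = build_intervals(nday)
        d = _data(lo, up, cluster=rng.integers(0, 5, n),
                  score=rng.integers(0, 4, n).astype(float))
        theta = [0.4, np.log(0.6), np.log(0.25), np.log(0.1)]
        l9 = hw.loglik(theta, d, "intercept_slope", nodes=9)
        l15 = hw.loglik(theta, d, "intercept_slope", nodes=15)
        assert abs(l9 - l15) < 1e-6

    def test_equivariance_shift_of_log_bounds(self, rng):
        """Adding c to all log bounds and to the intercept leaves every
        cluster's likelihood unchanged."""
        n = 40
        lo = rng.normal(size=n)
        up = lo + rng.uniform(0.1, 1.5, n)
        cl = rng.integers(0, 4, n)
        c = 0.37
        d = _data(lo, up, cluster=cl)
        d_shift = _data(lo + c, up + c, cluster=cl)
        th = np.array([0.2, np.log(0.8), np.log(0.2)])
        th_shift = th + np.array([c, 0, 0])
        np.testing.assert_allclose(
            cluster_loglik(th, d, "intercept"),
            cluster_loglik(th_shift, d_shift, "intercept"), atol=1e-10)


class TestFitting:
    def test_exact_data_reduces_to_ols(self, rng):
        n = 1500
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=n)])
        y = X @ np.array([0.4, 0.12, -0.3]) + 0.6 * rng.normal(size=n)
        d = _data(y, y, X=X, cluster=rng.integers(0, 10, n),
                  exact=np.ones(n, bool))
        fit = fit_interval_lognormal(d, random_effects="none", gtol=1e-7)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(fit.coef.to_numpy() - ols)) < 1e-4
        assert fit.sigma == pytest.approx(np.std(y - X @ ols), rel=1e-3)

    def test_sigma_consistent_on_large_uncensored_sample(self, rng):
        y = 0.3 + 0.55 * rng.normal(size=100_000)
        d = _data(y, y, exact=np.ones(len(y), bool))
        fit = fit_interval_lognormal(d, random_effects="none",
                                     compute_sandwich=False)
        assert fit.sigma == pytest.approx(np.std(y), rel=0.02)

    def test_intercept_only_median_from_symmetric_intervals(self):
        # intervals (1, 4) and a near-degenerate one at 2: both centred at
        # log 2, so the fitted median is 2 days
        lo = np.array([np.log(1.0), np.log(2.0) - 1e-6])
        up = np.array([np.log(4.0), np.log(2.0) + 1e-6])
        d = _data(lo, up, cluster=[0, 1])
        fit = fit_interval_lognormal(d, random_effects="none",
                                     compute_sandwich=False)
        m, _, _ = hw.predicted_median(fit, se_kind="model")
        assert m == pytest.approx(2.0, rel=1e-3)

    def test_interval_fit_matches_lifelines(self, rng):
        """Fixed-effects interval-censored log-normal fit cross-checked
        against an independent AFT implementation."""
        lifelines = pytest.importorskip("lifelines")
        n = 800
        x = rng.integers(0, 2, n).astype(float)
        t = np.exp(0.4 + 0.25 * x + 0.6 * rng.normal(size=n))
        nday = np.maximum(1, np.ceil(t)).astype(int)
        keep = nday <= 7  # avoid mixing censoring conventions across packages
        nday, x = nday[keep], x[keep]
        lo, up = build_intervals(nday)
        X = np.column_stack([np.ones(len(x)), x])
        d = _data(lo, up, X=X, cluster=np.arange(len(x)),
                  names=["intercept", "x"])
        fit = fit_interval_lognormal(d, random_effects="none",
                                     compute_sandwich=False, gtol=1e-7)
        df = pd.DataFrame({"lb": np.where(nday == 1, 1e-9, nday - 1.0),
                           "ub": nday.astype(float), "x": x})
        ll = lifelines.LogNormalAFTFitter()
        ll.fit_interval_censoring(df, lower_bound_col="lb", upper_bound_col="ub")
        mu = ll.params_["mu_"]
        assert fit.coef["intercept"] == pytest.approx(mu["Intercept"], abs=2e-3)
        assert fit.coef["x"] == pytest.approx(mu["x"], abs=2e-3)
        assert fit.sigma == pytest.approx(
            np.exp(ll.params_["sigma_"]["Intercept"]), rel=5e-3)

    def test_random_effects_need_two_hospitals(self):
        d = _data([0.0], [0.5])
        with pytest.raises(ValueError, match="2 hospitals"):
            fit_interval_lognormal(d, random_effects="intercept")

    def test_constant_design_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            _data([0.0, 0.1], [0.5, 0.6],
                  X=np.column_stack([np.ones(2), np.zeros(2)]),
                  cluster=[0, 1])


@pytest.fixture(scope="module")
def demand_fit():
    df = hw.simulate_aft_dataset(25, 60, tau_intercept=0.08,
                                 category_probs=(0.4, 0.35, 0.15, 0.1),
                                 rng=np.random.default_rng(5))
    return hw.fit_aft(df, covariates=None, random_effects="intercept",
                      nodes=9), df


class TestEffects:
    def test_percent_change_null_and_printed_transform(self, demand_fit):
        fit, _ = demand_fit
        # beta = log(1.22) corresponds to a printed +22.0%
        assert (np.exp(np.log(1.22)) - 1) * 100 == pytest.approx(22.0)
        e = hw.percent_change(fit, "demand[medium]")
        assert e.pct_change == pytest.approx((np.exp(e.beta) - 1) * 100)
        assert e.ci_low < e.pct_change < e.ci_high

    def test_ci_endpoints_transform(self):
        """beta=0.1 with se=0.05 gives the CI ((e^0.002-1), (e^0.198-1))*100."""
        V = np.diag([1e-4, 0.05 ** 2, 1e-4])
        stub = hw.AFTFit(
            params=np.array([0.0, 0.1, np.log(0.6)]),
            param_names=["intercept", "demand[medium]", "log_sigma"],
            sigma=0.6, tau={}, loglik=0.0, vcov_model=V, vcov_sandwich=V,
            n_obs=10, n_clusters=2, converged=True, message="",
            random_effects="none", nodes=9, adaptive=True)
        e = hw.percent_change(stub, "demand[medium]")
        assert e.ci_low == pytest.approx((np.exp(0.002) - 1) * 100, abs=1e-9)
        assert e.ci_high == pytest.approx((np.exp(0.198) - 1) * 100, abs=1e-9)
        # a null coefficient is a 0% change
        stub.params[1] = 0.0
        assert hw.percent_change(stub, "demand[medium]").pct_change == 0.0

    def test_median_ratio_identity(self, demand_fit):
        """predicted_median ratio minus one equals percent_change / 100,
        exactly, for every demand level."""
        fit, _ = demand_fit
        m_ref, _, _ = hw.predicted_median(fit, {"demand_category": "benchmark"})
        for cat in ("medium", "high", "excessive"):
            m, _, _ = hw.predicted_median(fit, {"demand_category": cat})
            e = hw.percent_change(fit, f"demand[{cat}]")
            assert m / m_ref - 1 == pytest.approx(e.pct_change / 100, abs=1e-12)

    def test_unseen_level_raises(self, demand_fit):
        fit, _ = demand_fit
        with pytest.raises(ValueError, match="unseen level"):
            hw.predicted_median(fit, {"demand_category": "catastrophic"})

    def test_modal_profile(self, demand_fit):
        fit, df = demand_fit
        prof = modal_profile(df, fit)
        assert prof["demand_category"] in set(df["demand_category"])


class TestSandwich:
    def test_duplicating_clusters_halves_covariance(self, rng):
        df = hw.simulate_aft_dataset(40, 25, tau_intercept=0.1, rng=rng)
        data = IntervalData.from_episodes(df, covariates=None)
        fit = fit_interval_lognormal(data, random_effects="none",
                                     compute_sandwich=False)
        dup = pd.concat([df, df.assign(
            index_hospital_id=df["index_hospital_id"] + "dup")],
            ignore_index=True)
        data2 = IntervalData.from_episodes(dup, covariates=None)
        V1, A1, B1 = sandwich_vcov(fit.params, data, "none")
        V2, A2, B2 = sandwich_vcov(fit.params, data2, "none")
        # near-zero cross terms need an absolute tolerance set by the scale
        np.testing.assert_allclose(A2, 2 * A1, rtol=1e-3,
                                   atol=1e-5 * np.abs(A1).max())
        np.testing.assert_allclose(B2, 2 * B1, rtol=1e-3,
                                   atol=1e-5 * np.abs(B1).max())
        np.testing.assert_allclose(V2, V1 / 2, rtol=0.02)

    def test_single_cluster_rejected(self):
        d = _data([0.0, 0.1], [0.5, 0.7])
        with pytest.raises(ValueError, match="2 clusters"):
            sandwich_vcov([0.1, np.log(0.5)], d, "none")
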