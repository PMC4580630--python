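"""ADF/KPSS battery: oracle equivalence, calibration, decision rule."""

import warnings

import numpy as np
import pytest
from statsmodels.tsa.stattools import adfuller, kpss as sm_kpss

import txdeter as td
from txdeter.unitroot import Variant, adf_test, kpss_test


def _ar1(T, phi, seed, trend=0.0):
    rng = np.random.default_rng(seed)
    y = np.zeros(T)
    for t in range(1, T):
        y[t] = phi * y[t - 1] + rng.standard_normal()
    return y + trend * np.arange(T)


class TestADF:
    def test_tau_equals_brute_force_ols_t_ratio(self):
        y = _ar1(30, 0.5, seed=99)
        res = adf_test(y, "drift", max_lag=0, selection="fixed")["tau"]
        # brute-force oracle: OLS of dy on [1, y_{t-1}]
        dy = np.diff(y)
        X = np.column_stack([np.ones(29), y[:-1]])
        b, *_ = np.linalg.lstsq(X, dy, rcond=None)
        e = dy - X @ b
        s2 = e @ e / (29 - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.statistic == pytest.approx(b[1] / se, rel=1e-11)

    @pytest.mark.parametrize(
        "variant,regression", [("none", "n"), ("drift", "c"), ("trend", "ct")]
    )
    def test_matches_statsmodels_with_aic_selection(self, variant, regression):
        y = np.cumsum(np.random.default_rng(42).standard_normal(144))
        mine = adf_test(y, variant)["tau"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_stat, _, used_lag, *_ = adfuller(y, regression=regression, autolag="AIC")
        assert mine.statistic == pytest.approx(sm_stat, rel=1e-9)
        assert mine.lags == used_lag

    def test_exact_linear_series_raises_not_silent(self):
        y = 5.0 * np.arange(1, 61)
        with pytest.raises(Exception, match="degenerate|perfect"):
            adf_test(y, "trend")

    def test_joint_statistics_present_per_variant(self):
        y = _ar1(100, 0.5, seed=3)
        assert set(adf_test(y, "none")) == {"tau"}
        assert set(adf_test(y, "drift")) == {"tau", "phi1"}
        assert set(adf_test(y, "trend")) == {"tau", "phi2", "phi3"}

    def test_phi_statistics_reject_for_stationary_series(self):
        y = _ar1(300, 0.5, seed=11)
        res = adf_test(y, "trend")
        assert res["phi3"].statistic > res["phi3"].critical_values[0.05]

    def test_critical_values_strictly_ordered(self):
        y = _ar1(100, 0.5, seed=3)
        for r in adf_test(y, "trend").values():
            cv = r.critical_values
            if r.statistic_kind == "tau":
                assert cv[0.01] < cv[0.05] < cv[0.10]
            else:
                assert cv[0.01] > cv[0.05] > cv[0.10]


class TestKPSS:
    def test_matches_partial_sum_oracle_no_correction(self):
        y = _ar1(30, 0.3, seed=17)
        res = kpss_test(y, "drift", bandwidth="none")
        e = y - y.mean()
        eta = np.sum(np.cumsum(e) ** 2) / (30**2 * (e @ e / 30))
        assert res.statistic == pytest.approx(eta, rel=1e-12)

    @pytest.mark.parametrize("variant,regression", [("drift", "c"), ("trend", "ct")])
    @pytest.mark.parametrize("bandwidth", ["short", "long"])
    def test_matches_statsmodels_bartlett(self, variant, regression, bandwidth):
        y = np.cumsum(np.random.default_rng(5).standard_normal(144))
        mine = kpss_test(y, variant, bandwidth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_stat, *_ = sm_kpss(y, regression=regression, nlags=mine.lags)
        assert mine.statistic == pytest.approx(sm_stat, rel=1e-9)

    def test_bandwidths_at_monthly_sample_size(self):
        y = _ar1(144, 0.3, seed=1)
        assert kpss_test(y, "drift", "short").lags == 4
        assert kpss_test(y, "drift", "long").lags == 13
        assert kpss_test(y, "drift", "none").lags == 0

    def test_constant_series_gives_zero_with_flag(self):
        res = kpss_test(np.full(40, 3.0), "drift", "none")
        assert res.statistic == 0.0
        assert res.degenerate

    def test_rejects_random_walk_fails_to_reject_stationary(self):
        rw = np.cumsum(np.random.default_rng(8).standard_normal(300))
        assert kpss_test(rw, "drift", "long").rejects(0.05)
        stat = _ar1(300, 0.3, seed=8)
        assert not kpss_test(stat, "drift", "long").rejects(0.05)


class TestBattery:
    def test_random_walk_recommends_first_differencing(self):
        rw = td.generate_random_walk(144, seed=7)
        rep = td.battery(rw)
        assert rep.d == 1
        assert rep.D == 0

    def test_random_walks_mostly_recommend_differencing(self):
        """The d=1 recommendation should dominate under the unit-root null
        (KPSS-long power limits keep it below 100% at T=144)."""
        hits = sum(
            td.battery(td.generate_random_walk(144, seed=s)).d == 1
            for s in range(30)
        )
        assert hits / 30 >= 0.5

    def test_trend_stationary_recommends_level_model_with_trend(self):
        y = _ar1(144, 0.5, seed=21, trend=0.5)
        rep = td.battery(td.MonthlySeries("y", (1994, 1), y))
        assert rep.d == 0
        assert rep.include_deterministic_trend

    def test_battery_is_deterministic_and_has_nine_rows(self, default_panel):
        r1 = td.battery(default_panel.homicides)
        r2 = td.battery(default_panel.homicides)
        assert len(r1.results) == 12  # 3 tau + 3 joint + 6 KPSS rows
        frame = r1.to_frame()
        assert frame.equals(r2.to_frame())
        # nine distinct tests: 3 ADF regressions + 6 KPSS variants
        assert (frame["test"] == "KPSS").sum() == 6

    def test_recommendation_pure_function_of_results(self, default_panel):
        rep = td.battery(default_panel.homicides)
        adf_ok = any(
            r.rejects(0.05)
            for r in rep.results
            if r.statistic_kind == "tau" and r.variant in (Variant.DRIFT, Variant.TREND)
        )
        kpss_long = next(
            r for r in rep.results
            if r.family == "KPSS" and r.variant is Variant.DRIFT and r.lags == 13
        )
        expected_d = 0 if (adf_ok or not kpss_long.rejects(0.05)) else 1
        assert rep.d == expected_d


class TestSizeCalibration:
    def test_adf_size_on_random_walks(self):
        """ADF(drift) at 5% should reject in ~5% of pure random walks."""
        rejections = 0
        n = 500
        for s in range(n):
            rw = np.cumsum(np.random.default_rng(1_000 + s).standard_normal(144))
            rejections += adf_test(rw, "drift")["tau"].rejects(0.05)
        assert 0.03 <= rejections / n <= 0.07

    def test_kpss_size_on_stationary_ar(self):
        """KPSS long-bandwidth level test should keep size <= 10% under
        stationarity (AR(1), phi = 0.5)."""
        rejections = 0
        n = 500
        for s in range(n):
            y = _ar1(144, 0.5, seed=2_000 + s)
            rejections += kpss_test(y, "drift", "long").rejects(0.05)
        assert rejections / n <= 0.10


class TestSeasonalDecision:
    def test_heuristic_rule(self):
        from txdeter.unitroot import decide_seasonal_differencing

        assert decide_seasonal_differencing(0.93, 224.0, 231.0, False) == 0
        assert decide_seasonal_differencing(0.93, 224.0, 231.0, True) == 0
        assert decide_seasonal_differencing(1.01, 224.0, 200.0, True) == 1
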