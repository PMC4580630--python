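"""Monthly-series container, differencing, ACF/PACF and Ljung-Box."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.diagnostic import acorr_ljungbox

import txdeter as td
from txdeter.core import format_month, parse_month


class TestMonthlySeries:
    def test_month_codes_align_with_positions(self):
        s = td.MonthlySeries("h", (1994, 1), np.arange(30.0))
        assert s.month_at(0) == "1994(1)"
        assert s.month_at(11) == "1994(12)"
        assert s.month_at(12) == "1995(1)"
        assert s.end == (1996, 6)
        assert s.position_of("1995(7)") == 18

    @given(year=st.integers(1800, 2200), month=st.integers(1, 12))
    @settings(max_examples=60, derandomize=True)
    def test_month_code_round_trip(self, year, month):
        assert parse_month(format_month(year, month)) == (year, month)

    def test_trend_regressor_is_one_based(self):
        s = td.MonthlySeries("h", (2000, 6), np.zeros(5))
        assert s.trend().tolist() == [1, 2, 3, 4, 5]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            td.MonthlySeries("h", (2000, 1), [1.0, np.nan, 3.0])

    def test_window_and_lag(self):
        s = td.MonthlySeries("h", (1994, 1), np.arange(24.0))
        w = s.window("1994(7)", "1995(6)")
        assert len(w) == 12 and w.values[0] == 6.0
        lagged = s.lag(3)
        assert lagged.start == (1994, 4)
        assert lagged.values[0] == 0.0


class TestDifference:
    def test_constant_series_differences_to_zero(self):
        s = td.MonthlySeries("c", (1994, 1), np.full(20, 7.0))
        assert np.all(td.difference(s, 1).values == 0.0)

    def test_simple_example(self):
        s = td.MonthlySeries("x", (1994, 1), [1.0, 2.0, 4.0, 7.0])
        d = td.difference(s, 1)
        assert d.values.tolist() == [1.0, 2.0, 3.0]
        assert d.start == (1994, 2)

    def test_first_and_seasonal_composition(self):
        s = td.MonthlySeries("x", (1994, 1), np.arange(40.0) ** 1.5)
        d = td.difference(td.difference(s, 1), 12)
        assert len(d) == len(s) - 13
        assert d.start == (1995, 2)

    def test_lag_too_long_raises(self):
        s = td.MonthlySeries("x", (1994, 1), np.arange(5.0))
        with pytest.raises(ValueError, match="5 observations"):
            td.difference(s, 5)

    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, derandomize=True)
    def test_differencing_is_linear(self, a, b, seed):
        r = np.random.default_rng(seed)
        x = td.MonthlySeries("x", (1990, 1), r.normal(size=30))
        y = td.MonthlySeries("y", (1990, 1), r.normal(size=30))
        combo = td.MonthlySeries("z", (1990, 1), a * x.values + b * y.values)
        lhs = td.difference(combo, 1).values
        rhs = a * td.difference(x, 1).values + b * td.difference(y, 1).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestAcfPacf:
    def test_fixed_series_matches_direct_formula(self):
        vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        prof = td.acf_pacf(td.MonthlySeries("x", (1994, 1), vals), max_lag=3)
        xc = vals - vals.mean()
        denom = np.sum(xc**2)
        for k in range(4):
            expected = np.sum(xc[k:] * xc[: len(vals) - k]) / denom
            assert prof.acf[k] == pytest.approx(expected, abs=1e-12)
        assert prof.acf[0] == 1.0

    def test_white_noise_has_small_correlations(self, rng):
        x = td.MonthlySeries("w", (1900, 1), rng.standard_normal(10_000))
        prof = td.acf_pacf(x, 20)
        # ~5% of lags may exceed the 2/sqrt(T) band; 3/sqrt(T) excursions rare
        assert np.all(np.abs(prof.acf[1:]) < 3 / np.sqrt(10_000))

    def test_constant_series_flagged_degenerate(self):
        prof = td.acf_pacf(td.MonthlySeries("c", (1994, 1), np.full(50, 2.0)), 5)
        assert prof.degenerate
        assert np.all(np.isnan(prof.acf))

    def test_bounds(self, rng):
        x = td.MonthlySeries("w", (1900, 1), rng.standard_normal(500))
        prof = td.acf_pacf(x, 24)
        assert np.all(np.abs(prof.acf) <= 1.0 + 1e-12)
        assert np.all(np.abs(prof.pacf) <= 1.0 + 1e-12)


class TestLjungBox:
    def test_matches_direct_formula_and_statsmodels(self, rng):
        x = rng.standard_normal(100)
        rep = td.ljung_box(x, 5, fitted_params=0)
        # independent oracle: explicit sum-of-products formula
        xc = x - x.mean()
        denom = np.sum(xc**2)
        r = np.array([np.sum(xc[k:] * xc[:-k]) / denom for k in range(1, 6)])
        q_direct = 100 * 102 * np.cumsum(r**2 / (100 - np.arange(1, 6)))
        np.testing.assert_allclose(rep.statistic, q_direct, rtol=1e-10)
        sm = acorr_ljungbox(x, lags=5, model_df=0)
        np.testing.assert_allclose(rep.statistic, sm["lb_stat"], rtol=1e-8)
        np.testing.assert_allclose(rep.pvalue, sm["lb_pvalue"], rtol=1e-8)

    def test_single_lag_formula_value(self, rng):
        # T=100 with r_1 = 0.3 gives Q = 100*102*0.09/99
        x = rng.standard_normal(100)
        rep = td.ljung_box(x, 1, fitted_params=0)
        xc = x - x.mean()
        r1 = np.sum(xc[1:] * xc[:-1]) / np.sum(xc**2)
        assert rep.statistic[0] == pytest.approx(100 * 102 * r1**2 / 99, rel=1e-12)

    def test_df_accounting_and_nan_pvalues(self, rng):
        rep = td.ljung_box(rng.standard_normal(80), 8, fitted_params=5)
        assert np.all(np.isnan(rep.pvalue[:5]))
        assert np.all(~np.isnan(rep.pvalue[5:]))
        assert rep.df[5] == 1

    def test_statistic_nondecreasing_in_lag(self, rng):
        rep = td.ljung_box(rng.standard_normal(200), 16)
        assert np.all(np.diff(rep.statistic) >= -1e-12)

    @given(shift=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=25, derandomize=True)
    def test_invariant_to_adding_constant(self, shift):
        x = np.random.default_rng(7).standard_normal(60)
        q0 = td.ljung_box(x, 6).statistic
        q1 = td.ljung_box(x + shift, 6).statistic
        np.testing.assert_allclose(q0, q1, rtol=1e-8, atol=1e-10)


class TestPanelIO:
    def test_round_trip(self, tmp_path, rng):
        panel = {
            "homicides": td.MonthlySeries("homicides", (1994, 1), rng.poisson(150, 24).astype(float)),
            "executions": td.MonthlySeries("executions", (1994, 1), rng.poisson(2, 24).astype(float)),
        }
        path = tmp_path / "panel.csv"
        td.write_panel_csv(path, panel)
        back = td.read_panel_csv(path)
        for name in panel:
            assert back[name].start == panel[name].start
            np.testing.assert_array_equal(back[name].values, panel[name].values)

    def test_gap_error_names_month(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "year,month,homicides\n1994,1,100\n1994,2,110\n1994,4,105\n"
        )
        with pytest.raises(ValueError, match=r"1994\(3\)"):
            td.read_panel_csv(path)
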