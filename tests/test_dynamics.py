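"""Impact multipliers, impulse responses and Monte Carlo error bands."""

import numpy as np
import pandas as pd
import pytest

import txdeter as td
from txdeter.arima import SarimaxFit, SarimaxSpec
from txdeter.dynamics import multiplier_from


def make_fit(betas, ar=(), sar=0.0, ma=(), sma=0.0, sigma2=1.0, nobs=144,
             bse_scale=0.1):
    """Hand-built fit object with a diagonal parameter covariance, for
    exercising the response machinery at exactly known coefficients."""
    spec = SarimaxSpec(
        (len(ar), 0, len(ma)),
        (1 if sar else 0, 0, 1 if sma else 0),
        include_mean=True,
        include_trend=False,
        exog_terms=tuple(("x", lag) for lag in sorted(betas)),
    )
    names = ["intercept"] + [
        "x" if lag == 0 else f"x[t-{lag}]" for lag in sorted(betas)
    ]
    values = [100.0] + [betas[lag] for lag in sorted(betas)]
    for i, a in enumerate(ar, 1):
        names.append(f"ar.L{i}")
        values.append(a)
    for i, m in enumerate(ma, 1):
        names.append(f"ma.L{i}")
        values.append(m)
    if sar:
        names.append("ar.S.L12")
        values.append(sar)
    if sma:
        names.append("ma.S.L12")
        values.append(sma)
    free = list(names)
    names.append("sigma2")
    values.append(sigma2)
    params = pd.Series(values, index=names, dtype=float)
    cov = np.eye(len(free)) * bse_scale**2
    T = nobs
    return SarimaxFit(
        spec=spec,
        params=params,
        bse=pd.Series(np.sqrt(np.r_[np.diag(cov), 0.1]), index=names),
        cov_params=cov,
        free_param_names=free,
        sigma2=sigma2,
        llf=0.0,
        nobs=T,
        k_params=len(names),
        residuals=np.zeros(T),
        fittedvalues=np.zeros(T),
        endog=np.zeros(T),
        endog_name="y",
        start=(1994, 1),
        converged=True,
        stationary=True,
        invertible=True,
    )


class TestImpactMultiplier:
    @pytest.mark.parametrize(
        "betas,phis,expected",
        [
            ([-1.31], [0.14], -1.31 / 0.86),
            ([-1.0], [], -1.0),
            ([-0.90, -0.82], [0.32, 0.15, 0.30], (-1.72) / 0.23),
        ],
    )
    def test_known_values(self, betas, phis, expected):
        assert multiplier_from(betas, phis) == pytest.approx(expected, rel=1e-12)

    def test_on_fit_object_sums_lags(self):
        f = make_fit({0: -0.9, 1: -0.82}, ar=(0.32, 0.15, 0.30))
        assert td.impact_multiplier(f, "x") == pytest.approx(-1.72 / 0.23, rel=1e-12)

    def test_seasonal_excluded_by_default_included_on_request(self):
        f = make_fit({0: -1.0}, ar=(0.5,), sar=0.5)
        assert td.impact_multiplier(f, "x") == pytest.approx(-2.0)
        assert td.impact_multiplier(f, "x", include_seasonal=True) == pytest.approx(-4.0)

    def test_explosive_denominator_raises(self):
        f = make_fit({0: -1.0}, ar=(0.7, 0.4))
        with pytest.raises(ValueError, match="explosive|undefined"):
            td.impact_multiplier(f, "x")


class TestModalIrf:
    def test_static_model_is_pulse_only(self):
        f = make_fit({0: -1.3})
        irf = td.modal_irf(f, "x", horizon=6)
        np.testing.assert_allclose(irf.path, [-1.3, 0, 0, 0, 0, 0], atol=1e-15)

    def test_lagged_input_shifts_pulse(self):
        f = make_fit({1: -0.8})
        irf = td.modal_irf(f, "x", horizon=4)
        np.testing.assert_allclose(irf.path, [0, -0.8, 0, 0], atol=1e-15)

    def test_ar1_closed_form_to_machine_precision(self):
        beta, phi = -1.3, 0.6
        f = make_fit({0: beta}, ar=(phi,))
        irf = td.modal_irf(f, "x", horizon=40)
        np.testing.assert_allclose(
            irf.path, beta * phi ** np.arange(40), rtol=1e-13, atol=1e-14
        )

    def test_cumulative_is_running_sum(self):
        f = make_fit({0: -1.0}, ar=(0.3, 0.2))
        irf = td.modal_irf(f, "x", horizon=24)
        np.testing.assert_allclose(irf.cumulative, np.cumsum(irf.path), atol=1e-14)

    def test_long_horizon_cumulative_converges_to_multiplier(self):
        f = make_fit({0: -0.93}, ar=(0.31, 0.15, 0.31))
        irf = td.modal_irf(f, "x", horizon=240)
        assert irf.cumulative[-1] == pytest.approx(
            td.impact_multiplier(f, "x"), abs=1e-6
        )

    def test_seasonal_terms_enter_recursion(self):
        f_plain = make_fit({0: -1.0}, ar=(0.3,))
        f_seasonal = make_fit({0: -1.0}, ar=(0.3,), sar=0.9)
        p0 = td.modal_irf(f_plain, "x", horizon=14).path
        p1 = td.modal_irf(f_seasonal, "x", horizon=14).path
        np.testing.assert_allclose(p0[:12], p1[:12], atol=1e-14)
        assert p1[12] != pytest.approx(p0[12])  # seasonal echo at lag 12


class TestMcIrf:
    def test_reproducible_under_seed(self):
        f = make_fit({0: -1.0}, ar=(0.3,), sigma2=4.0)
        a = td.mc_irf(f, "x", draws=300, seed=11)
        b = td.mc_irf(f, "x", draws=300, seed=11)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_zero_coefficient_model_bands_straddle_zero_symmetrically(self):
        f = make_fit({0: 0.0}, sigma2=1.0, bse_scale=0.05)
        irf = td.mc_irf(f, "x", draws=4000, seed=2)
        assert np.allclose(irf.path, 0.0)
        assert irf.covers_zero()
        np.testing.assert_allclose(irf.lower, -irf.upper, atol=0.15)

    def test_residual_uncertainty_widens_bands_not_modal(self):
        f = make_fit({0: -1.0}, ar=(0.3,), sigma2=225.0, bse_scale=0.05)
        full = td.mc_irf(f, "x", draws=1500, seed=3)
        params_only = td.mc_irf(
            f, "x", draws=1500, seed=3, include_residual_uncertainty=False
        )
        np.testing.assert_array_equal(full.path, params_only.path)
        width_full = (full.upper - full.lower).mean()
        width_po = (params_only.upper - params_only.lower).mean()
        assert width_full > 10 * width_po

    def test_median_of_noise_free_ensemble_near_modal(self):
        f = make_fit({0: -1.0}, ar=(0.3,), bse_scale=0.02)
        irf = td.mc_irf(
            f, "x", draws=4000, seed=5, include_residual_uncertainty=False
        )
        med = np.median(irf.draws, axis=0)
        np.testing.assert_allclose(med, irf.path, atol=0.02)

    def test_band_endpoints_stable_in_draw_count(self):
        f = make_fit({0: -1.0}, ar=(0.3,), sigma2=1.0, bse_scale=0.05)
        small = td.mc_irf(f, "x", draws=2000, seed=7)
        large = td.mc_irf(f, "x", draws=20_000, seed=7)
        mc_err = 3.0 / np.sqrt(2000)
        assert np.max(np.abs(small.lower - large.lower)) < 10 * mc_err

    def test_unstable_fit_rejected_draws_error(self):
        # both AR terms one quarter of a standard error inside the unit
        # circle: most joint draws land outside and are rejected
        f = make_fit({0: -1.0}, ar=(0.95,), sar=0.95, bse_scale=0.2)
        with pytest.raises(RuntimeError, match="non-stationary"):
            td.mc_irf(f, "x", draws=400, seed=9)


class TestShapeBands:
    def test_perfectly_correlated_draws_reproduce_pointwise_band(self):
        # constructed ensemble: every draw is a scalar multiple of one shape
        rng = np.random.default_rng(13)
        shape = np.sin(np.linspace(0.3, 2.0, 12))
        scores = rng.normal(0.0, 2.0, 5000)
        ens = np.outer(scores, shape)
        modal = np.zeros(12)
        base = td.ImpulseResponse(
            input_name="x", horizon=12, path=modal,
            cumulative=np.cumsum(modal), impact_multiplier=0.0,
            lower=np.quantile(ens, 0.16, axis=0),
            upper=np.quantile(ens, 0.84, axis=0),
            coverage=0.68, band_method="pointwise", draws=ens,
        )
        shaped = td.shape_bands(base)
        np.testing.assert_allclose(shaped.lower, base.lower, atol=0.02)
        np.testing.assert_allclose(shaped.upper, base.upper, atol=0.02)

    def test_requires_enough_draws(self):
        base = td.ImpulseResponse(
            input_name="x", horizon=12, path=np.zeros(12),
            cumulative=np.zeros(12), impact_multiplier=0.0,
            coverage=0.68, draws=np.zeros((5, 12)),
        )
        with pytest.raises(ValueError, match="draws"):
            td.shape_bands(base)

    def test_shape_band_tighter_under_serial_correlation(self):
        f = make_fit({0: -1.0}, ar=(0.6,), sigma2=25.0, bse_scale=0.05)
        irf = td.mc_irf(f, "x", draws=3000, seed=21)
        shaped = td.shape_bands(irf)
        assert (shaped.upper - shaped.lower).mean() < (irf.upper - irf.lower).mean()
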