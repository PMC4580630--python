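"""Impact multipliers and Monte Carlo impulse-response error bands.

The fitted transfer-function model is read in its lagged-output form
(the form in which its coefficient tables are printed),

    y_t = c + tau t + sum_l beta_l x_{t-l} + phi(L) Phi(L^12) y-terms + MA noise,

so a one-month, one-unit pulse in the input produces a response that decays
through the full (nonseasonal x seasonal) autoregressive recursion.  The
long-run impact multiplier is the classical sum(beta) / (1 - sum(phi)) with
nonseasonal AR terms only; the seasonal AR enters the month-by-month
recursion but is deliberately excluded from the multiplier denominator
(``include_seasonal=True`` gives the full long-run gain instead).

Uncertainty is quantified by Monte Carlo: parameters are drawn from their
asymptotic normal (non-stationary draws rejected and redrawn), the
innovation variance from its scaled inverse chi-square, and each draw's
shocked-minus-baseline path carries innovation noise at the drawn sigma.
Bands are pointwise equal-tailed percentile bands (default 68%, roughly
one standard deviation), or likelihood-shape bands built from the first
principal component of the draw ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .arima import SarimaxFit

__all__ = [
    "ImpulseResponse",
    "impact_multiplier",
    "multiplier_from",
    "modal_irf",
    "mc_irf",
    "shape_bands",
]


@dataclass(frozen=True)
class ImpulseResponse:
    """A 0..H-1 month response path to a single one-unit input pulse.

    ``path`` is the modal (point-estimate, noise-free) response in output
    units per unit input; ``cumulative`` its running sum; ``lower/upper``
    the band at ``coverage``; ``draws`` the retained ensemble (draws x H)
    or None.
    """

    input_name: str
    horizon: int
    path: np.ndarray
    cumulative: np.ndarray
    impact_multiplier: float
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    coverage: float | None = None
    band_method: str | None = None
    draws: np.ndarray | None = None
    n_rejected: int = 0
    seed: int | None = None

    def covers_zero(self) -> bool:
        """True iff the band contains zero at every horizon."""
        if self.lower is None:
            raise ValueError("no band attached")
        return bool(np.all((self.lower <= 0.0) & (self.upper >= 0.0)))

    def to_frame(self) -> pd.DataFrame:
        d = {"horizon": np.arange(self.horizon), "modal": self.path,
             "cumulative": self.cumulative}
        if self.lower is not None:
            d["lower"], d["upper"] = self.lower, self.upper
        return pd.DataFrame(d)


def multiplier_from(betas, phis) -> float:
    """sum(beta) / (1 - sum(phi)) from raw coefficient values."""
    betas = np.atleast_1d(np.asarray(betas, float))
    phis = np.atleast_1d(np.asarray(phis, float))
    denom = 1.0 - phis.sum()
    if denom <= 0:
        raise ValueError(
            f"nonseasonal AR coefficients sum to {phis.sum():.3f} >= 1; "
            "the long-run multiplier is undefined (explosive denominator)"
        )
    return float(betas.sum() / denom)


def impact_multiplier(
    fit: SarimaxFit, input_name: str, include_seasonal: bool = False
) -> float:
    """Long-run change in the output per one-unit sustained input change.

    Default follows the classical convention: only nonseasonal AR terms in
    the denominator.  ``include_seasonal=True`` divides also by
    (1 - seasonal AR), the full long-run gain of the recursion.
    """
    betas = list(fit.exog_coefs(input_name).values())
    value = multiplier_from(betas, fit.ar_coefs)
    if include_seasonal:
        denom = 1.0 - fit.seasonal_ar
        if denom <= 0:
            raise ValueError("seasonal AR >= 1; full long-run gain undefined")
        value /= denom
    return value


def _full_ar_poly(ar: np.ndarray, seasonal_ar: float, period: int = 12) -> np.ndarray:
    """Coefficients a_j of the expanded product phi(L)*Phi(L^s), j >= 1."""
    ns = np.r_[1.0, -np.asarray(ar, float)]
    sea = np.zeros(period + 1)
    sea[0] = 1.0
    sea[period] = -seasonal_ar
    return -np.convolve(ns, sea)[1:]


def _full_ma_poly(ma: np.ndarray, seasonal_ma: float, period: int = 12) -> np.ndarray:
    """Coefficients m_j of theta(L)*Theta(L^s), j >= 1 (statsmodels sign)."""
    ns = np.r_[1.0, np.asarray(ma, float)]
    sea = np.zeros(period + 1)
    sea[0] = 1.0
    sea[period] = seasonal_ma
    return np.convolve(ns, sea)[1:]


def _recurse(pulse: np.ndarray, a: np.ndarray, horizon: int) -> np.ndarray:
    r = np.zeros(horizon)
    for h in range(horizon):
        acc = pulse[h] if h < pulse.size else 0.0
        jmax = min(h, a.size)
        for j in range(1, jmax + 1):
            acc += a[j - 1] * r[h - j]
        r[h] = acc
    return r


def _irf_path(betas: dict[int, float], ar, sar, horizon: int) -> np.ndarray:
    pulse = np.zeros(max(horizon, max(betas) + 1))
    for lag, b in betas.items():
        pulse[lag] = b
    return _recurse(pulse, _full_ar_poly(np.atleast_1d(ar), float(sar)), horizon)


def modal_irf(fit: SarimaxFit, input_name: str, horizon: int = 12) -> ImpulseResponse:
    """Noise-free response path to a one-month unit pulse, months 0..H-1.

    Seasonal AR dynamics are included in the recursion; moving-average
    terms act on the innovations only and do not transmit the input pulse.
    """
    betas = fit.exog_coefs(input_name)
    path = _irf_path(betas, fit.ar_coefs, fit.seasonal_ar, horizon)
    return ImpulseResponse(
        input_name=input_name,
        horizon=horizon,
        path=path,
        cumulative=np.cumsum(path),
        impact_multiplier=impact_multiplier(fit, input_name),
    )


def _draw_params(fit: SarimaxFit, rng: np.random.Generator):
    """One stationarity-accepted parameter draw from the asymptotic normal."""
    mean = fit.params[fit.free_param_names].to_numpy()
    chol = np.linalg.cholesky(
        fit.cov_params + 1e-12 * np.eye(len(mean))
    )
    p = fit.spec.order[0]
    names = fit.free_param_names
    idx_ar = [names.index(f"ar.L{i}") for i in range(1, p + 1) if f"ar.L{i}" in names]
    idx_sar = names.index("ar.S.L12") if "ar.S.L12" in names else None
    while True:
        draw = mean + chol @ rng.standard_normal(mean.size)
        ar = draw[idx_ar] if idx_ar else np.zeros(0)
        sar = draw[idx_sar] if idx_sar is not None else 0.0
        yield draw, ar, sar


def _is_stationary(ar: np.ndarray, sar: float) -> bool:
    from .arima import _poly_stationary

    return _poly_stationary(ar) and _poly_stationary(np.atleast_1d(sar))


def mc_irf(
    fit: SarimaxFit,
    input_name: str,
    horizon: int = 12,
    draws: int = 5000,
    coverage: float = 0.68,
    include_residual_uncertainty: bool = True,
    seed: int | None = None,
    keep_draws: bool = True,
) -> ImpulseResponse:
    """Monte Carlo impulse response with pointwise percentile error bands.

    Per draw: sample the free parameters from N(theta_hat, V_hat),
    rejecting and redrawing non-stationary configurations (count logged in
    ``n_rejected``); sample sigma^2 from its scaled inverse chi-square with
    T - k degrees of freedom; simulate the H-month shocked-minus-baseline
    response — the deterministic recursion at the drawn parameters plus,
    when ``include_residual_uncertainty`` is on, SARMA innovation noise at
    the drawn sigma applied to the shocked path (the baseline is
    noise-free, so the band embodies forecast-style uncertainty).  The
    modal path always comes from the point estimates, noise-free.
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    if fit.cov_params.size == 0:
        raise ValueError("fit carries no parameter covariance matrix")
    rng = np.random.default_rng(seed)
    modal = modal_irf(fit, input_name, horizon)

    names = fit.free_param_names
    lag_keys = {
        lag: (input_name if lag == 0 else f"{input_name}[t-{lag}]")
        for name, lag in fit.spec.exog_terms
        if name == input_name
    }
    if not lag_keys:
        raise KeyError(f"input {input_name!r} has no estimated coefficient")
    beta_idx = {lag: names.index(key) for lag, key in lag_keys.items()}
    q = fit.spec.order[2]
    ma_idx = [names.index(f"ma.L{i}") for i in range(1, q + 1) if f"ma.L{i}" in names]
    sma_idx = names.index("ma.S.L12") if "ma.S.L12" in names else None

    df_sig = max(fit.nobs - fit.k_params, 1)
    sampler = _draw_params(fit, rng)
    ens = np.empty((draws, horizon))
    n_rejected = 0
    for d in range(draws):
        while True:
            draw, ar, sar = next(sampler)
            if _is_stationary(ar, float(sar)):
                break
            n_rejected += 1
            if n_rejected > max(100, 2 * draws):
                raise RuntimeError(
                    f"more than half of parameter draws non-stationary "
                    f"({n_rejected} rejections by draw {d})"
                )
        betas = {lag: draw[i] for lag, i in beta_idx.items()}
        path = _irf_path(betas, ar, float(sar), horizon)
        if include_residual_uncertainty:
            sigma2_d = fit.sigma2 * df_sig / rng.chisquare(df_sig)
            ma = draw[ma_idx] if ma_idx else np.zeros(0)
            sma = draw[sma_idx] if sma_idx is not None else 0.0
            a = _full_ar_poly(ar, float(sar))
            m = _full_ma_poly(ma, float(sma))
            eps = rng.normal(0.0, np.sqrt(sigma2_d), horizon)
            noise = np.zeros(horizon)
            for h in range(horizon):
                acc = eps[h]
                for j in range(1, min(h, a.size) + 1):
                    acc += a[j - 1] * noise[h - j]
                for j in range(1, min(h, m.size) + 1):
                    acc += m[j - 1] * eps[h - j]
                noise[h] = acc
            path = path + noise
        ens[d] = path

    if n_rejected > draws:  # rejection fraction above one half
        raise RuntimeError(
            f"{n_rejected}/{n_rejected + draws} parameter draws were "
            "non-stationary; the fitted model is too close to the unit circle"
        )
    alpha = (1.0 - coverage) / 2.0
    lower = np.quantile(ens, alpha, axis=0)
    upper = np.quantile(ens, 1.0 - alpha, axis=0)
    return replace(
        modal,
        lower=lower,
        upper=upper,
        coverage=coverage,
        band_method="pointwise",
        draws=ens if keep_draws else None,
        n_rejected=n_rejected,
        seed=seed,
    )


def shape_bands(response: ImpulseResponse) -> ImpulseResponse:
    """Likelihood-shape error bands from the draw ensemble.

    Eigendecompose the ensemble covariance across horizons; the band is the
    modal path shifted by the first principal component scaled by the
    (1-coverage)/2 and 1-(1-coverage)/2 percentiles of the draws' scores on
    that component.  With serially correlated response uncertainty this
    band is tighter than the pointwise one while preserving the path shape.
    """
    if response.draws is None:
        raise ValueError("draw ensemble was not retained; rerun with keep_draws=True")
    ens = response.draws
    if ens.shape[0] < response.horizon:
        raise ValueError(
            f"need at least H={response.horizon} draws, have {ens.shape[0]}"
        )
    coverage = response.coverage if response.coverage is not None else 0.68
    centered = ens - ens.mean(axis=0)
    cov = centered.T @ centered / (ens.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    pc1 = vecs[:, -1]
    # score deviations from the modal path (not the ensemble mean), so the
    # band is anchored on the path it decorates
    scores = (ens - response.path) @ pc1
    alpha = (1.0 - coverage) / 2.0
    lo_s, hi_s = np.quantile(scores, [alpha, 1.0 - alpha])
    band_a = response.path + lo_s * pc1
    band_b = response.path + hi_s * pc1
    return replace(
        response,
        lower=np.minimum(band_a, band_b),
        upper=np.maximum(band_a, band_b),
        band_method="shape",
    )
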