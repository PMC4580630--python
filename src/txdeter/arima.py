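"""Regression with seasonal ARMA errors ("ARIMA transfer function" models).

The workhorse is exact Gaussian maximum likelihood through the state-space
form (statsmodels SARIMAX).  Deterministic terms (intercept, linear trend)
and lagged input series enter as regressors, so the model is

    y_t = c + tau * t + sum_i beta_i x_{i,t-l_i} + u_t,
    phi(L) Phi(L^12) u_t = theta(L) Theta(L^12) eps_t,

i.e. regression with SARMA errors in the mean-subtraction parameterisation:
with a stationary error process the estimated intercept sits near the
(detrended) sample mean, the convention used in classical intervention
analysis tables.  The innovations-form intercept of a pure ARMA fit would
instead be c * phi(1) * Phi(1); ``SarimaxFit.innovations_intercept`` does
that conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MonthlySeries, WhitenessReport, ljung_box

__all__ = [
    "SarimaxSpec",
    "SarimaxFit",
    "ConvergenceError",
    "fit",
    "r_squared",
    "likelihood_ratio",
    "lr_test",
    "residual_gate",
    "model_table",
]

INTERCEPT = "intercept"
TREND = "t"


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimiser fails to converge.

    Carries the optimiser trace dict as ``.trace``.
    """

    def __init__(self, message: str, trace: dict | None = None):
        super().__init__(message)
        self.trace = trace or {}


@dataclass(frozen=True)
class SarimaxSpec:
    """Orders and regressors of one transfer-function model.

    ``exog_terms`` is a tuple of (series name, lag) pairs; lag 0 is the
    contemporaneous input.  Period is fixed at 12 (monthly seasonality).
    """

    order: tuple[int, int, int] = (3, 0, 0)
    seasonal_order: tuple[int, int, int] = (1, 0, 1)
    include_mean: bool = True
    include_trend: bool = True
    exog_terms: tuple[tuple[str, int], ...] = ()
    period: int = 12

    def __post_init__(self):
        p, d, q = self.order
        P, D, Q = self.seasonal_order
        if d not in (0, 1) or D not in (0, 1):
            raise ValueError("d and D must be 0 or 1")
        if min(p, q, P, Q) < 0:
            raise ValueError("ARMA orders must be nonnegative")
        if self.period != 12:
            raise ValueError("only monthly (period 12) models are supported")

    @property
    def n_arma_params(self) -> int:
        p, _, q = self.order
        P, _, Q = self.seasonal_order
        return p + q + P + Q

    def exog_names(self) -> list[str]:
        names = []
        if self.include_mean:
            names.append(INTERCEPT)
        if self.include_trend:
            names.append(TREND)
        for name, lag in self.exog_terms:
            names.append(name if lag == 0 else f"{name}[t-{lag}]")
        return names


@dataclass
class SarimaxFit:
    """A fitted regression-with-seasonal-ARMA-errors model.

    ``params``/``bse`` are name-indexed (regressors first, then ar.L*,
    ma.L*, ar.S.L12, ma.S.L12, sigma2); ``cov_params`` covers the free
    parameters excluding sigma2, in ``free_param_names`` order — that is
    what the Monte Carlo impulse-response engine samples from.
    """

    spec: SarimaxSpec
    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    free_param_names: list[str]
    sigma2: float
    llf: float
    nobs: int
    k_params: int
    residuals: np.ndarray
    fittedvalues: np.ndarray
    endog: np.ndarray
    endog_name: str
    start: tuple[int, int]
    converged: bool
    stationary: bool
    invertible: bool
    optimizer_trace: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        """AIC = -2 LLF + 2k with k counting regression, ARMA and sigma2."""
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def ar_coefs(self) -> np.ndarray:
        p = self.spec.order[0]
        return np.array([self.params.get(f"ar.L{i}", 0.0) for i in range(1, p + 1)])

    @property
    def ma_coefs(self) -> np.ndarray:
        q = self.spec.order[2]
        return np.array([self.params.get(f"ma.L{i}", 0.0) for i in range(1, q + 1)])

    @property
    def seasonal_ar(self) -> float:
        return float(self.params.get("ar.S.L12", 0.0))

    @property
    def seasonal_ma(self) -> float:
        return float(self.params.get("ma.S.L12", 0.0))

    def exog_coefs(self, input_name: str) -> dict[int, float]:
        """Estimated coefficients of one input, keyed by lag."""
        out = {}
        for name, lag in self.spec.exog_terms:
            if name == input_name:
                key = name if lag == 0 else f"{name}[t-{lag}]"
                out[lag] = float(self.params[key])
        if not out:
            raise KeyError(f"input {input_name!r} has no estimated coefficient")
        return out

    @property
    def innovations_intercept(self) -> float:
        """Mean intercept converted to the innovations-form constant."""
        c = float(self.params.get(INTERCEPT, 0.0))
        return c * (1 - self.ar_coefs.sum()) * (1 - self.seasonal_ar)

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"coef": self.params, "se": self.bse})
        df["p"] = 2 * stats.norm.sf(np.abs(df["coef"] / df["se"]))
        return df


def _build_exog(
    series: MonthlySeries,
    spec: SarimaxSpec,
    exog: dict[str, MonthlySeries] | None,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Trim the target and assemble the regressor matrix on common support."""
    exog = exog or {}
    max_lag = max((lag for _, lag in spec.exog_terms), default=0)
    # positions of `series` usable by every lagged regressor
    y_start = series.start_serial
    lo, hi = y_start, y_start + len(series) - 1
    for name, lag in spec.exog_terms:
        if name not in exog:
            raise KeyError(f"exogenous series {name!r} not supplied")
        x = exog[name]
        lo = max(lo, x.start_serial + lag)
        hi = min(hi, x.start_serial + len(x) - 1 + lag)
    if hi - lo + 1 < 2 * spec.n_arma_params + 5:
        raise ValueError("too few overlapping observations after lagging")
    i0 = lo - y_start
    y = series.values[i0 : hi - y_start + 1]
    T = y.size
    cols = []
    if spec.include_mean:
        cols.append(np.ones(T))
    if spec.include_trend:
        cols.append(np.arange(1, T + 1, dtype=float))
    for name, lag in spec.exog_terms:
        x = exog[name]
        j0 = lo - lag - x.start_serial
        cols.append(x.values[j0 : j0 + T])
    X = np.column_stack(cols) if cols else np.empty((T, 0))
    from .core import _from_serial

    return y, X, _from_serial(lo)


def _poly_stationary(coefs: np.ndarray) -> bool:
    """True iff 1 - c1 z - ... - cp z^p has all roots outside the unit circle."""
    coefs = np.trim_zeros(np.asarray(coefs, float), "b")
    if coefs.size == 0:
        return True
    roots = np.roots(np.r_[-coefs[::-1], 1.0])
    return bool(np.all(np.abs(roots) > 1.0 + 1e-9))


def fit(
    series: MonthlySeries,
    spec: SarimaxSpec,
    exog: dict[str, MonthlySeries] | None = None,
    strict: bool = True,
) -> SarimaxFit:
    """Estimate the model by exact Gaussian ML in state-space form.

    Starting values follow the statsmodels method-of-moments rule, so fits
    are deterministic.  Non-convergence raises :class:`ConvergenceError`
    (carrying the optimiser trace) unless ``strict=False``; a non-invertible
    MA or non-stationary AR at the optimum only attaches a warning flag.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    y, X, start = _build_exog(series, spec, exog)
    names = spec.exog_names()
    X_named = pd.DataFrame(X, columns=names) if X.shape[1] else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            y,
            exog=X_named,
            order=spec.order,
            seasonal_order=(*spec.seasonal_order, spec.period),
            trend="n",
        )
        res = model.fit(disp=0, method="lbfgs", maxiter=500)
        trace = dict(res.mle_retvals) if res.mle_retvals else {}
        converged = bool(trace.get("converged", True))
        if not converged:
            res = model.fit(disp=0, method="bfgs", maxiter=500,
                            start_params=res.params)
            trace = dict(res.mle_retvals) if res.mle_retvals else {}
            converged = bool(trace.get("converged", True))
    if not converged and strict:
        raise ConvergenceError(
            f"ML estimation of {spec} did not converge", trace
        )

    pretty = list(res.param_names)
    params = pd.Series(np.asarray(res.params, float), index=pretty)
    bse = pd.Series(np.asarray(res.bse, float), index=pretty)
    free = [n for n in pretty if n != "sigma2"]
    cov = pd.DataFrame(
        np.asarray(res.cov_params(), float), index=pretty, columns=pretty
    ).loc[free, free].to_numpy()

    p = spec.order[0]
    ar = np.array([params.get(f"ar.L{i}", 0.0) for i in range(1, p + 1)])
    ma = np.array(
        [params.get(f"ma.L{i}", 0.0) for i in range(1, spec.order[2] + 1)]
    )
    sar = np.array([params.get("ar.S.L12", 0.0)])
    sma = np.array([params.get("ma.S.L12", 0.0)])
    stationary = _poly_stationary(ar) and _poly_stationary(sar)
    invertible = _poly_stationary(-ma) and _poly_stationary(-sma)
    if not stationary:
        warnings.warn("AR polynomial roots on/inside the unit circle", stacklevel=2)
    if not invertible:
        warnings.warn("MA polynomial not invertible at the optimum", stacklevel=2)

    resid = np.asarray(res.resid, float)
    return SarimaxFit(
        spec=spec,
        params=params,
        bse=bse,
        cov_params=cov,
        free_param_names=free,
        sigma2=float(params["sigma2"]),
        llf=float(res.llf),
        nobs=int(res.nobs),
        k_params=len(params),
        residuals=resid,
        fittedvalues=np.asarray(res.fittedvalues, float),
        endog=y,
        endog_name=series.name,
        start=start,
        converged=converged,
        stationary=stationary,
        invertible=invertible,
        optimizer_trace=trace,
    )


def r_squared(fit_result: SarimaxFit) -> float:
    """R^2 = 1 - sigma2_hat / sample variance of the undifferenced target."""
    var_y = float(np.var(fit_result.endog, ddof=1))
    if var_y == 0:
        raise ValueError("target series has zero variance; R^2 undefined")
    return 1.0 - fit_result.sigma2 / var_y


def likelihood_ratio(llf_restricted: float, llf_full: float, df: int):
    """LR statistic 2*(LLF_full - LLF_restricted) with chi-square p-value."""
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (llf_full - llf_restricted)
    return stat, df, float(stats.chi2.sf(max(stat, 0.0), df))


def lr_test(restricted: SarimaxFit, full: SarimaxFit):
    """Likelihood-ratio test of a nested model pair fitted on one sample."""
    r_names = set(restricted.params.index)
    f_names = set(full.params.index)
    if not r_names <= f_names:
        extra = sorted(r_names - f_names)
        raise ValueError(f"models are not nested: restricted has extra {extra}")
    if restricted.nobs != full.nobs:
        raise ValueError(
            f"estimation samples differ ({restricted.nobs} vs {full.nobs}); "
            "refit on the common sample before comparing"
        )
    df = full.k_params - restricted.k_params
    if df <= 0:
        raise ValueError("full model adds no parameters")
    return likelihood_ratio(restricted.llf, full.llf, df)


def residual_gate(
    fit_result: SarimaxFit, max_lag: int = 16, alpha: float = 0.05
) -> tuple[WhitenessReport, bool]:
    """Ljung–Box whiteness gate on the fitted model's residuals.

    Degrees of freedom are reduced by the number of ARMA parameters; the
    gate passes iff every defined lag up to ``max_lag`` has p > ``alpha``.
    """
    report = ljung_box(
        fit_result.residuals, max_lag, fitted_params=fit_result.spec.n_arma_params
    )
    return report, report.passes(alpha)


def model_table(fits: dict[str, SarimaxFit]) -> pd.DataFrame:
    """Side-by-side coefficient table in the classical two-row layout
    (coefficient with its standard error beneath), plus sigma2, LLF, AIC, R^2.
    """
    rows: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for col, f in fits.items():
        for name in f.params.index:
            if name == "sigma2":
                continue
            if name not in rows:
                rows[name] = {}
                order.append(name)
            rows[name][col] = f"{f.params[name]:.3f} ({f.bse[name]:.3f})"
    footer = {
        "sigma2": {c: f"{f.sigma2:.1f}" for c, f in fits.items()},
        "LLF": {c: f"{f.llf:.2f}" for c, f in fits.items()},
        "AIC": {c: f"{f.aic:.2f}" for c, f in fits.items()},
        "R2": {c: f"{r_squared(f):.2f}" for c, f in fits.items()},
    }
    data = {name: rows[name] for name in order} | footer
    return pd.DataFrame(data).T.reindex(columns=list(fits))
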