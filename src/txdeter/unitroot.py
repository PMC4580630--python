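"""ADF / KPSS unit-root battery and the differencing decision rule.

The battery runs nine tests on one series — three augmented Dickey–Fuller
regressions (no deterministics; drift; drift + linear trend, the latter two
with their joint F-type Phi statistics) and six KPSS variants (level/trend
null, each with a short, long or no Bartlett correction) — and converts the
results into a recommendation for the ARIMA specification: whether to first
difference (d), whether to seasonally difference (D), and whether to carry
a deterministic linear trend.

Critical values are embedded: Dickey–Fuller tau and Phi tables at their
moderate-sample row (appropriate for T of roughly 100–500 months) and the
asymptotic KPSS table.  ADF rejects in the left tail for tau statistics and
the right tail for Phi statistics; KPSS — whose null is stationarity —
rejects in the right tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import MonthlySeries

__all__ = [
    "Variant",
    "UnitRootResult",
    "BatteryReport",
    "adf_test",
    "kpss_test",
    "battery",
    "decide_seasonal_differencing",
]


class Variant(str, Enum):
    NONE = "none"      # no constant, no trend
    DRIFT = "drift"    # constant only
    TREND = "trend"    # constant + linear trend


# Dickey-Fuller tau and Phi critical values, moderate-sample row
# (valid for monthly samples of about 100-500 observations).
_ADF_TAU_CRIT = {
    Variant.NONE: {0.01: -2.58, 0.05: -1.95, 0.10: -1.62},
    Variant.DRIFT: {0.01: -3.46, 0.05: -2.88, 0.10: -2.57},
    Variant.TREND: {0.01: -3.99, 0.05: -3.43, 0.10: -3.13},
}
_ADF_PHI_CRIT = {
    "phi1": {0.01: 6.52, 0.05: 4.63, 0.10: 3.81},   # joint (c, rho) in drift model
    "phi2": {0.01: 6.22, 0.05: 4.75, 0.10: 4.07},   # joint (c, tau, rho) in trend model
    "phi3": {0.01: 8.43, 0.05: 6.49, 0.10: 5.47},   # joint (tau, rho) in trend model
}
# KPSS asymptotic critical values (level / trend null).
_KPSS_CRIT = {
    Variant.DRIFT: {0.01: 0.739, 0.05: 0.463, 0.10: 0.347},
    Variant.TREND: {0.01: 0.216, 0.05: 0.146, 0.10: 0.119},
}

_LEVELS = (0.01, 0.05, 0.10)


@dataclass(frozen=True)
class UnitRootResult:
    """One unit-root / stationarity test outcome.

    ``statistic_kind`` is ``"tau"`` (t-ratio on rho-1, left-tailed),
    ``"phi1"``/``"phi2"``/``"phi3"`` (Dickey–Fuller joint F-type,
    right-tailed) or ``"eta"`` (KPSS, right-tailed).
    """

    family: str                      # "ADF" | "KPSS"
    variant: Variant
    statistic_kind: str
    statistic: float
    lags: int                        # ADF augmentation order or KPSS bandwidth
    critical_values: dict[float, float]
    degenerate: bool = False

    def rejects(self, level: float = 0.05) -> bool:
        cv = self.critical_values[level]
        if self.statistic_kind == "tau":
            return self.statistic < cv
        return self.statistic > cv

    @property
    def reject_flags(self) -> dict[float, bool]:
        return {lv: self.rejects(lv) for lv in _LEVELS}


def _ols(y: np.ndarray, X: np.ndarray):
    """Plain OLS returning (beta, ssr, XtX_inv); raises on rank deficiency."""
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid), XtX_inv


def _adf_design(y: np.ndarray, variant: Variant, k: int, offset: int):
    """Design for Delta y_t on deterministics, y_{t-1}, Delta y_{t-1..k}.

    ``offset`` drops extra leading rows so different lag orders can be
    compared on a common estimation sample.
    """
    dy = np.diff(y)
    start = max(k, offset)
    lhs = dy[start:]
    cols = []
    if variant is not Variant.NONE:
        cols.append(np.ones_like(lhs))
    if variant is Variant.TREND:
        cols.append(np.arange(start + 2, y.size + 1, dtype=float))
    ylag = y[start:-1]
    cols.append(ylag)
    for j in range(1, k + 1):
        cols.append(dy[start - j : dy.size - j])
    return lhs, np.column_stack(cols), len(cols) - (k + 1)  # n deterministic cols


def _schwert_maxlag(T: int) -> int:
    return int(np.floor(12 * (T / 100.0) ** 0.25))


def adf_test(
    series: MonthlySeries | np.ndarray,
    variant: Variant | str = Variant.DRIFT,
    max_lag: int | None = None,
    selection: str = "aic",
) -> dict[str, UnitRootResult]:
    """Augmented Dickey–Fuller test.

    Fits Delta y_t = c + tau*t + (rho-1) y_{t-1} + sum gamma_j Delta y_{t-j}
    with deterministics per ``variant``.  The augmentation order is chosen
    by AIC over 0..max_lag on a common sample (max_lag defaults to the
    Schwert rule floor(12 (T/100)^{1/4})), or fixed at ``max_lag`` when
    ``selection="fixed"``; the chosen order is then re-estimated on the
    longest available sample.

    Returns a dict with the ``"tau"`` result and, for the drift/trend
    variants, the joint ``"phi1"`` or ``"phi2"``/``"phi3"`` results whose
    restricted models impose the unit-root null (and zero deterministics).
    """
    variant = Variant(variant)
    y = series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)
    T = y.size
    if T < 25:
        raise ValueError(f"ADF needs at least 25 observations, got {T}")
    if np.ptp(y) == 0:
        raise ValueError("ADF is undefined on a constant series")

    kmax = _schwert_maxlag(T) if max_lag is None else int(max_lag)
    if selection == "fixed":
        k = kmax
    elif selection == "aic":
        # compare on the common sample implied by kmax
        best = None
        for k_try in range(kmax + 1):
            lhs, X, _ = _adf_design(y, variant, k_try, offset=kmax)
            try:
                _, ssr, _ = _ols(lhs, X)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "degenerate ADF regression (exactly collinear design); "
                    "the series may be a perfect deterministic function of time"
                ) from err
            n = lhs.size
            if ssr <= 0:
                raise np.linalg.LinAlgError(
                    "perfect fit in ADF regression; statistic undefined"
                )
            aic = n * np.log(ssr / n) + 2 * X.shape[1]
            if best is None or aic < best[0]:
                best = (aic, k_try)
        k = best[1]
    else:
        raise ValueError("selection must be 'aic' or 'fixed'")

    lhs, X, n_det = _adf_design(y, variant, k, offset=k)
    try:
        beta, ssr, XtX_inv = _ols(lhs, X)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "degenerate ADF regression (exactly collinear design)"
        ) from err
    n, p = lhs.size, X.shape[1]
    if ssr <= 0 or n <= p:
        raise np.linalg.LinAlgError("perfect fit in ADF regression; statistic undefined")
    s2 = ssr / (n - p)
    idx_rho = n_det  # y_{t-1} column follows the deterministic columns
    tau = beta[idx_rho] / np.sqrt(s2 * XtX_inv[idx_rho, idx_rho])

    out = {
        "tau": UnitRootResult(
            "ADF", variant, "tau", float(tau), k, dict(_ADF_TAU_CRIT[variant])
        )
    }

    def phi(restrict_cols: list[int], kind: str) -> UnitRootResult:
        keep = [j for j in range(p) if j not in restrict_cols]
        if keep:
            _, ssr_r, _ = _ols(lhs, X[:, keep])
        else:
            ssr_r = float(lhs @ lhs)
        q = len(restrict_cols)
        stat = ((ssr_r - ssr) / q) / (ssr / (n - p))
        return UnitRootResult(
            "ADF", variant, kind, float(stat), k, dict(_ADF_PHI_CRIT[kind])
        )

    if variant is Variant.DRIFT:
        out["phi1"] = phi([0, idx_rho], "phi1")          # c = 0, rho = 1
    elif variant is Variant.TREND:
        out["phi2"] = phi([0, 1, idx_rho], "phi2")       # c = tau = 0, rho = 1
        out["phi3"] = phi([1, idx_rho], "phi3")          # tau = 0, rho = 1
    return out


def _kpss_bandwidth(T: int, bandwidth: str | int) -> int:
    if isinstance(bandwidth, int):
        return bandwidth
    if bandwidth == "none":
        return 0
    if bandwidth == "short":
        return int(np.floor(4 * (T / 100.0) ** 0.25))
    if bandwidth == "long":
        return int(np.floor(12 * (T / 100.0) ** 0.25))
    raise ValueError("bandwidth must be 'none', 'short', 'long' or an int")


def kpss_test(
    series: MonthlySeries | np.ndarray,
    variant: Variant | str = Variant.DRIFT,
    bandwidth: str | int = "short",
) -> UnitRootResult:
    """KPSS stationarity test (null: stationary around a level or trend).

    eta = T^{-2} sum_t S_t^2 / s^2(l), with S_t the partial sums of the
    residuals from regressing the series on an intercept (level null) or
    intercept + trend (trend null), and s^2(l) the Bartlett-window long-run
    variance at bandwidth l: 0 ("none"), floor(4 (T/100)^{1/4}) ("short") or
    floor(12 (T/100)^{1/4}) ("long").
    """
    variant = Variant(variant)
    if variant is Variant.NONE:
        raise ValueError("KPSS requires a drift or trend variant")
    y = series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)
    T = y.size
    if T < 25:
        raise ValueError(f"KPSS needs at least 25 observations, got {T}")
    lag = _kpss_bandwidth(T, bandwidth)

    X = np.ones((T, 1))
    if variant is Variant.TREND:
        X = np.column_stack([X, np.arange(1, T + 1, dtype=float)])
    beta, _, _ = _ols(y, X)
    e = y - X @ beta
    if np.allclose(e, 0):
        return UnitRootResult(
            "KPSS", variant, "eta", 0.0, lag, dict(_KPSS_CRIT[variant]), degenerate=True
        )
    S = np.cumsum(e)
    s2 = e @ e / T
    for j in range(1, lag + 1):
        w = 1.0 - j / (lag + 1.0)
        s2 += 2.0 * w * (e[j:] @ e[:-j]) / T
    eta = (S @ S) / (T**2 * s2)
    return UnitRootResult("KPSS", variant, "eta", float(eta), lag, dict(_KPSS_CRIT[variant]))


@dataclass(frozen=True)
class BatteryReport:
    """The nine-test battery and the specification it recommends.

    ``results`` holds, in battery order: ADF(none) tau; ADF(drift) tau and
    phi1; ADF(trend) tau, phi2 and phi3; KPSS drift/trend x short/long/none.
    The recommendation is a pure function of the results via the rule in
    :func:`battery`.
    """

    results: tuple[UnitRootResult, ...]
    d: int
    D: int
    include_deterministic_trend: bool

    def by_kind(self, family: str, variant: Variant, kind: str,
                lags: int | None = None) -> UnitRootResult:
        for r in self.results:
            if (r.family == family and r.variant == variant
                    and r.statistic_kind == kind
                    and (lags is None or r.lags == lags)):
                return r
        raise KeyError((family, variant, kind, lags))

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            rows.append(
                {
                    "test": r.family,
                    "version": f"{r.variant.value},{r.statistic_kind},lags={r.lags}",
                    "statistic": r.statistic,
                    "1%": r.critical_values[0.01],
                    "5%": r.critical_values[0.05],
                    "10%": r.critical_values[0.10],
                    "reject_5%": r.rejects(0.05),
                }
            )
        return pd.DataFrame(rows)


def battery(series: MonthlySeries, alpha: float = 0.05) -> BatteryReport:
    """Run the nine-test ADF/KPSS battery and recommend (d, D, trend).

    Decision rule (documented, deterministic):

    * ``d = 0`` if either deterministic-augmented ADF variant (drift or
      trend) rejects the unit root at ``alpha``, or the long-bandwidth
      level KPSS fails to reject stationarity; else ``d = 1``.
    * The deterministic trend is included if the joint trend/unit-root
      F-type statistic (phi3) rejects at ``alpha``.
    * ``D = 0`` always at this stage: there is no formal seasonal unit-root
      test in the battery; seasonal differencing is decided against the
      fitted baseline model via :func:`decide_seasonal_differencing`.
    """
    adf_none = adf_test(series, Variant.NONE)
    adf_drift = adf_test(series, Variant.DRIFT)
    adf_trend = adf_test(series, Variant.TREND)
    results = [
        adf_none["tau"],
        adf_drift["tau"],
        adf_drift["phi1"],
        adf_trend["tau"],
        adf_trend["phi2"],
        adf_trend["phi3"],
    ]
    for variant in (Variant.DRIFT, Variant.TREND):
        for bw in ("short", "long", "none"):
            results.append(kpss_test(series, variant, bw))

    kpss_long_level = next(
        r
        for r in results
        if r.family == "KPSS"
        and r.variant is Variant.DRIFT
        and r.lags == _kpss_bandwidth(len(series), "long")
    )
    stationary = (
        adf_drift["tau"].rejects(alpha)
        or adf_trend["tau"].rejects(alpha)
        or not kpss_long_level.rejects(alpha)
    )
    d = 0 if stationary else 1
    include_trend = adf_trend["phi3"].rejects(alpha)
    return BatteryReport(tuple(results), d, 0, include_trend)


def decide_seasonal_differencing(
    seasonal_ar: float,
    sigma2_undifferenced: float,
    sigma2_differenced: float,
    rival_residuals_white: bool,
) -> int:
    """Heuristic D decision mirroring the baseline-vs-rival comparison.

    Keep ``D = 0`` when the fitted seasonal AR coefficient is inside the
    unit circle and the seasonally differenced rival does not fit better
    (higher error variance, or serially correlated residuals); otherwise
    recommend ``D = 1``.
    """
    if abs(seasonal_ar) < 1 and (
        sigma2_differenced >= sigma2_undifferenced or not rival_residuals_white
    ):
        return 0
    return 1
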