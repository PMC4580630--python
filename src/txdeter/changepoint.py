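"""Multiple-structural-break regression (Bai–Perron) with BIC selection.

The model is a pure structural-change regression: y_t = z_t' delta_j + u_t
on regimes j = 1..m+1 delimited by unknown break dates T_1 < ... < T_m.
For a candidate number of breaks m the break dates are those that globally
minimise the total sum of squared residuals, found by dynamic programming
over a precomputed triangular table of segment SSRs; m itself is selected
by minimising BIC over m = 0..max_m.  Per-regime coefficients, plain
homoskedastic OLS standard errors and two-sided p-values are recomputed on
the final segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MonthlySeries

__all__ = [
    "BreakSpec",
    "RegimeEstimate",
    "BreakFit",
    "segment_ssr",
    "optimal_partition",
    "select_breaks",
    "default_min_segment",
]

_SSR_RIDGE_FLAG = "degenerate"


@dataclass(frozen=True)
class BreakSpec:
    """Switching-regressor specification for the break model.

    ``regressors`` are column names of the design (all coefficients switch
    across regimes); ``min_segment`` is the shortest admissible regime
    length h; ``max_breaks`` the largest m considered.
    """

    regressors: tuple[str, ...]
    min_segment: int
    max_breaks: int = 5

    def __post_init__(self):
        if self.min_segment < len(self.regressors) + 1:
            raise ValueError(
                "min_segment must be at least the number of regressors + 1"
            )
        if self.max_breaks < 0:
            raise ValueError("max_breaks must be >= 0")


def default_min_segment(T: int, n_regressors: int) -> int:
    """Standard 15% trimming, floored at identifiability: max(ceil(0.15 T), p+1)."""
    return max(int(np.ceil(0.15 * T)), n_regressors + 1)


def _segment_ols(y, Z):
    """OLS on one segment; pseudo-inverse fallback flags rank deficiency."""
    try:
        beta, res, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
        degenerate = rank < Z.shape[1]
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(Z) @ y
        degenerate = True
    r = y - Z @ beta
    return beta, float(r @ r), degenerate


def segment_ssr(y: np.ndarray, Z: np.ndarray, h: int) -> np.ndarray:
    """Triangular table of segment residual sums of squares.

    ``ssr[i, j]`` is the SSR of an OLS fit of y on Z over observations
    i..j inclusive, for all admissible segments of length >= h; shorter
    segments hold NaN.  Computed by recursive normal-equation updating:
    for each start i the cross-products accumulate over j, so the whole
    table costs O(T^2 p^2).  Rank-deficient segments get a pseudo-inverse
    solution (their SSR is still well defined).
    """
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    if Z.ndim != 2 or Z.shape[0] != y.size:
        raise ValueError("Z rows must align with y")
    T, p = Z.shape
    if h < p + 1:
        raise ValueError(f"min segment length {h} < regressors+1 = {p + 1}")
    ssr = np.full((T, T), np.nan)
    for i in range(T - h + 1):
        ZtZ = np.zeros((p, p))
        Zty = np.zeros(p)
        yty = 0.0
        for j in range(i, T):
            z = Z[j]
            ZtZ += np.outer(z, z)
            Zty += z * y[j]
            yty += y[j] * y[j]
            if j - i + 1 < h:
                continue
            try:
                beta = np.linalg.solve(ZtZ, Zty)
            except np.linalg.LinAlgError:
                beta = np.linalg.pinv(ZtZ) @ Zty
            ssr[i, j] = max(yty - beta @ Zty, 0.0)
    return ssr


def _mean_only_ssr(y: np.ndarray, h: int) -> np.ndarray:
    """Closed-form SSR table for the intercept-only model, via cumulative sums."""
    T = y.size
    cs = np.r_[0.0, np.cumsum(y)]
    cs2 = np.r_[0.0, np.cumsum(y * y)]
    i = np.arange(T)[:, None]
    j = np.arange(T)[None, :]
    n = j - i + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        s = cs[j + 1] - cs[i]
        ssr = cs2[j + 1] - cs2[i] - s * s / n
    ssr = np.where(n >= h, np.maximum(ssr, 0.0), np.nan)
    return ssr


def optimal_partition(
    ssr: np.ndarray, m: int, h: int
) -> tuple[list[int], float]:
    """Globally SSR-minimising split into m+1 segments by dynamic programming.

    Returns the break positions as the last index of each of the first m
    regimes (0-based), and the total SSR.  Ties break deterministically
    toward the earliest break positions.
    """
    T = ssr.shape[0]
    if m < 0 or (m + 1) * h > T:
        raise ValueError(f"{m} breaks infeasible with T={T}, h={h}")
    if m == 0:
        return [], float(ssr[0, T - 1])
    # cost[r][j]: minimal SSR of fitting r+1 segments to observations 0..j
    cost = np.full((m + 1, T), np.inf)
    argmin = np.zeros((m + 1, T), dtype=int)
    cost[0] = ssr[0]
    for r in range(1, m + 1):
        for j in range((r + 1) * h - 1, T):
            # previous segment ends at b, current runs b+1..j
            best, best_b = np.inf, -1
            for b in range(r * h - 1, j - h + 1):
                c = cost[r - 1, b] + ssr[b + 1, j]
                if c < best:  # strict: earliest b wins ties
                    best, best_b = c, b
            cost[r, j] = best
            argmin[r, j] = best_b
    total = float(cost[m, T - 1])
    breaks = []
    j = T - 1
    for r in range(m, 0, -1):
        b = int(argmin[r, j])
        breaks.append(b)
        j = b
    return breaks[::-1], total


@dataclass(frozen=True)
class RegimeEstimate:
    """Per-regime OLS estimates with segment-wise homoskedastic SEs."""

    start: int
    end: int
    coefs: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class BreakFit:
    """Selected break model plus the full BIC/SSR trace over m = 0..max_m."""

    spec: BreakSpec
    m: int
    breaks: list[int]                 # last index of regimes 1..m (0-based)
    regimes: list[RegimeEstimate]
    ssr: float
    sigma2: float                     # pooled SSR / (T - (m+1) p)
    r2: float
    bic_trace: dict[int, float]
    ssr_trace: dict[int, float]
    break_positions_trace: dict[int, list[int]] = field(default_factory=dict)
    series_start: tuple[int, int] | None = None

    def break_months(self) -> list[str]:
        """Break dates as YYYY(M) codes (last month of the earlier regime)."""
        if self.series_start is None:
            raise ValueError("no calendar anchor attached")
        anchor = MonthlySeries("anchor", self.series_start,
                               np.zeros(max(self.breaks, default=0) + 1 or 1))
        return [anchor.month_at(b) for b in self.breaks]

    def regime_table(self) -> pd.DataFrame:
        rows = {}
        for j, reg in enumerate(self.regimes, start=1):
            col = {}
            for name, c, s, p in zip(self.spec.regressors, reg.coefs, reg.se,
                                     reg.pvalues):
                col[name] = f"{c:.3f} ({s:.3f}) p={p:.3f}"
            rows[f"regime {j} [{reg.start}..{reg.end}]"] = col
        return pd.DataFrame(rows)


def select_breaks(
    y: np.ndarray | MonthlySeries,
    Z: np.ndarray | pd.DataFrame,
    spec: BreakSpec,
    count_break_dates_in_bic: bool = True,
) -> BreakFit:
    """Estimate break dates for m = 0..max_breaks and select m by BIC.

    BIC(m) = T ln(SSR_m / T) + k_m ln(T), with k_m counting the
    (m+1) * p regime coefficients, the innovation variance, and — by
    default — the m estimated break dates (switch off with
    ``count_break_dates_in_bic=False``; the literature uses both
    conventions).
    """
    start = None
    if isinstance(y, MonthlySeries):
        start = y.start
        yv = y.values
    else:
        yv = np.asarray(y, float)
    Zm = Z.to_numpy(float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    T, p = Zm.shape
    if p != len(spec.regressors):
        raise ValueError("Z columns must match spec.regressors")
    h = spec.min_segment

    if p == 1 and np.ptp(Zm) == 0 and Zm[0, 0] == 1.0:
        table = _mean_only_ssr(yv, h)
    else:
        table = segment_ssr(yv, Zm, h)

    bic_trace, ssr_trace, pos_trace = {}, {}, {}
    for m in range(spec.max_breaks + 1):
        if (m + 1) * h > T:
            break
        brk, total = optimal_partition(table, m, h)
        k = (m + 1) * p + 1 + (m if count_break_dates_in_bic else 0)
        bic_trace[m] = T * np.log(total / T) + k * np.log(T)
        ssr_trace[m] = total
        pos_trace[m] = brk
    m_star = min(bic_trace, key=bic_trace.get)
    breaks = pos_trace[m_star]

    bounds = [0, *[b + 1 for b in breaks], T]
    regimes = []
    for j in range(len(bounds) - 1):
        i0, i1 = bounds[j], bounds[j + 1]
        ys, Zs = yv[i0:i1], Zm[i0:i1]
        beta, ssr_j, degen = _segment_ols(ys, Zs)
        dof = max(i1 - i0 - p, 1)
        s2 = ssr_j / dof
        try:
            cov = s2 * np.linalg.inv(Zs.T @ Zs)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(Zs.T @ Zs)
            degen = True
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pv = 2 * stats.t.sf(np.abs(tstat), dof)
        regimes.append(RegimeEstimate(i0, i1 - 1, beta, se, pv, degen))

    total = ssr_trace[m_star]
    dof_total = T - (len(bounds) - 1) * p
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return BreakFit(
        spec=spec,
        m=m_star,
        breaks=breaks,
        regimes=regimes,
        ssr=total,
        sigma2=total / max(dof_total, 1),
        r2=1.0 - total / tss if tss > 0 else np.nan,
        bic_trace=bic_trace,
        ssr_trace=ssr_trace,
        break_positions_trace=pos_trace,
        series_start=start,
    )
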