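"""Monthly time-series container and serial-correlation diagnostics.

Everything downstream (unit-root battery, transfer-function models,
impulse responses, changepoints) works on :class:`MonthlySeries`, a named,
gap-free monthly-indexed real series.  Months are handled internally as a
0-based serial number ``year*12 + (month-1)``; all user-facing output uses
the ``"YYYY(M)"`` convention common in the intervention-analysis literature
(the first value of a series starting January 1994 is ``"1994(1)"``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

__all__ = [
    "MonthlySeries",
    "CorrelationProfile",
    "WhitenessReport",
    "difference",
    "acf_pacf",
    "ljung_box",
    "read_panel_csv",
    "write_panel_csv",
]

_MONTH_CODE_RE = re.compile(r"^(-?\d+)\((\d{1,2})\)$")


def _to_serial(year: int, month: int) -> int:
    if not 1 <= month <= 12:
        raise ValueError(f"month-of-year must be in 1..12, got {month}")
    return year * 12 + (month - 1)


def _from_serial(serial: int) -> tuple[int, int]:
    return divmod(serial, 12)[0], serial % 12 + 1


def format_month(year: int, month: int) -> str:
    """Render a calendar month as ``"YYYY(M)"``."""
    _to_serial(year, month)  # validates
    return f"{year}({month})"


def parse_month(code: str) -> tuple[int, int]:
    """Inverse of :func:`format_month`; raises on malformed codes."""
    m = _MONTH_CODE_RE.match(code.strip())
    if m is None:
        raise ValueError(f"not a YYYY(M) month code: {code!r}")
    year, month = int(m.group(1)), int(m.group(2))
    _to_serial(year, month)
    return year, month


@dataclass(frozen=True)
class MonthlySeries:
    """A named, contiguous monthly-indexed real-valued series.

    Parameters
    ----------
    name : str
        Label (e.g. ``"homicides"``).
    start : (int, int)
        Calendar month of the first observation as ``(year, month)`` with
        month in 1..12.
    values : array-like of float
        One value per month, no gaps, no missing values.
    """

    name: str
    start: tuple[int, int]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a 1-d sequence of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"series {self.name!r} contains missing/non-finite values; "
                "no imputation is performed"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))
        _to_serial(*self.start)

    def __len__(self) -> int:
        return self.values.size

    @property
    def start_serial(self) -> int:
        return _to_serial(*self.start)

    @property
    def end(self) -> tuple[int, int]:
        return _from_serial(self.start_serial + len(self) - 1)

    def month_at(self, position: int) -> str:
        """Month code ``"YYYY(M)"`` of 0-based ``position``."""
        if not 0 <= position < len(self):
            raise IndexError(f"position {position} outside 0..{len(self) - 1}")
        return format_month(*_from_serial(self.start_serial + position))

    def position_of(self, code: str) -> int:
        """0-based position of month code ``code``; raises if outside range."""
        pos = _to_serial(*parse_month(code)) - self.start_serial
        if not 0 <= pos < len(self):
            raise IndexError(f"{code} outside series range")
        return pos

    def trend(self) -> np.ndarray:
        """Deterministic time regressor t = 1..T aligned with positions."""
        return np.arange(1, len(self) + 1, dtype=float)

    def month_index(self) -> list[str]:
        return [self.month_at(i) for i in range(len(self))]

    def lag(self, k: int, name: str | None = None) -> "MonthlySeries":
        """Series of values lagged by ``k`` months (value at t is x_{t-k}),
        re-anchored so it aligns with the original index from position k."""
        if not 0 <= k < len(self):
            raise ValueError(f"lag {k} must be in 0..{len(self) - 1}")
        return MonthlySeries(
            name or f"{self.name}[t-{k}]",
            _from_serial(self.start_serial + k),
            self.values[: len(self) - k] if k else self.values,
        )

    def window(self, start: str, end: str) -> "MonthlySeries":
        """Sub-series between two month codes, inclusive."""
        i, j = self.position_of(start), self.position_of(end)
        if j < i:
            raise ValueError(f"window end {end} precedes start {start}")
        return MonthlySeries(self.name, parse_month(start), self.values[i : j + 1])

    def to_frame(self) -> pd.DataFrame:
        serials = self.start_serial + np.arange(len(self))
        return pd.DataFrame(
            {
                "year": serials // 12,
                "month": serials % 12 + 1,
                self.name: self.values,
            }
        )


def difference(series: MonthlySeries, lag: int = 1) -> MonthlySeries:
    """Apply the lag-``lag`` differencing operator x_t - x_{t-lag}.

    The output starts ``lag`` months after the input and is ``lag`` shorter.
    First differencing is ``lag=1``; seasonal differencing for monthly data
    is ``lag=12``; first-and-seasonal differencing composes the two.
    """
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if lag >= len(series):
        raise ValueError(
            f"cannot difference at lag {lag}: series {series.name!r} has "
            f"only {len(series)} observations"
        )
    out = series.values[lag:] - series.values[:-lag]
    return MonthlySeries(
        f"diff{lag}({series.name})",
        _from_serial(series.start_serial + lag),
        out,
    )


@dataclass(frozen=True)
class CorrelationProfile:
    """Sample ACF and PACF over lags 0..max_lag.

    ``acf`` uses the biased (1/T) covariance normalisation, the convention
    of standard ACF plots; ``pacf`` comes from the Durbin–Levinson
    recursion.  ``degenerate`` flags a (near-)constant input for which the
    correlations are undefined.
    """

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "acf": self.acf, "pacf": self.pacf})


def acf_pacf(series: MonthlySeries | np.ndarray, max_lag: int) -> CorrelationProfile:
    """Sample autocorrelation and partial autocorrelation profile.

    A constant series has zero variance and no defined correlations; it is
    returned with ``degenerate=True`` and NaN entries rather than silent
    zeros.
    """
    x = series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)
    T = x.size
    if not 0 < max_lag < T:
        raise ValueError(f"max_lag must be in 1..{T - 1}, got {max_lag}")
    lags = np.arange(max_lag + 1)
    if np.ptp(x) == 0 or np.var(x) < 1e-300:
        nan = np.full(max_lag + 1, np.nan)
        return CorrelationProfile(lags, nan, nan, degenerate=True)
    r = _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)
    # Levinson-Durbin on the biased ACF, so PACF is deterministic on short series
    p = _sm_pacf(x, nlags=max_lag, method="ldb")
    return CorrelationProfile(lags, r, p)


@dataclass(frozen=True)
class WhitenessReport:
    """Ljung–Box portmanteau statistics for residual whiteness, lags 1..L.

    ``df`` is the lag minus the number of fitted ARMA parameters; lags with
    df <= 0 carry no p-value (NaN).  Q is nondecreasing in L for nested lag
    sets since each term added is nonnegative.
    """

    lags: np.ndarray
    statistic: np.ndarray
    df: np.ndarray
    pvalue: np.ndarray
    fitted_params: int

    def passes(self, alpha: float = 0.05) -> bool:
        """True iff no defined lag rejects whiteness at level ``alpha``."""
        defined = ~np.isnan(self.pvalue)
        return bool(np.all(self.pvalue[defined] > alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "statistic": self.statistic,
                "df": self.df,
                "p": self.pvalue,
            }
        )


def ljung_box(
    residuals: np.ndarray | MonthlySeries,
    max_lag: int,
    fitted_params: int = 0,
) -> WhitenessReport:
    """Ljung–Box test of residual serial correlation at lags 1..max_lag.

    Q(L) = T (T+2) sum_{k<=L} r_k^2 / (T-k) with r_k the biased sample
    autocorrelations; under whiteness Q(L) ~ chi^2(L - fitted_params).
    """
    x = residuals.values if isinstance(residuals, MonthlySeries) else np.asarray(residuals, float)
    T = x.size
    if not 0 < max_lag < T:
        raise ValueError(f"max_lag must be in 1..{T - 1}")
    if fitted_params < 0:
        raise ValueError("fitted_params must be >= 0")
    r = _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)[1:]
    terms = r**2 / (T - np.arange(1, max_lag + 1))
    q = T * (T + 2) * np.cumsum(terms)
    lags = np.arange(1, max_lag + 1)
    df = lags - fitted_params
    p = np.where(df > 0, stats.chi2.sf(q, np.clip(df, 1, None)), np.nan)
    return WhitenessReport(lags, q, df.astype(int), p, fitted_params)


# ---------------------------------------------------------------------------
# CSV panel I/O: header row with columns year, month, <value columns>;
# months strictly increasing and contiguous.

def read_panel_csv(path) -> dict[str, MonthlySeries]:
    """Read a monthly panel CSV into one MonthlySeries per value column.

    Raises a ValueError naming the offending month on gaps or duplicates,
    and rejects missing values outright (no imputation).
    """
    df = pd.read_csv(path)
    required = {"year", "month"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel CSV must have columns {sorted(required)}")
    serials = df["year"].to_numpy(int) * 12 + df["month"].to_numpy(int) - 1
    gaps = np.flatnonzero(np.diff(serials) != 1)
    if gaps.size:
        y, m = _from_serial(serials[gaps[0]] + 1)
        raise ValueError(
            f"panel is not contiguous monthly: problem at/after {format_month(y, m)}"
        )
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; no imputation is performed")
    start = (int(df["year"].iloc[0]), int(df["month"].iloc[0]))
    return {
        c: MonthlySeries(c, start, df[c].to_numpy(float))
        for c in df.columns
        if c not in required
    }


def write_panel_csv(path, panel: dict[str, MonthlySeries]) -> None:
    """Write aligned series to the standard panel CSV layout."""
    names = list(panel)
    first = panel[names[0]]
    for s in panel.values():
        if s.start != first.start or len(s) != len(first):
            raise ValueError("all series in a panel must share start and length")
    df = first.to_frame()[["year", "month"]]
    for n in names:
        df[n] = panel[n].values
    df.to_csv(path, index=False)
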