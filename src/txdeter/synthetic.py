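"""Synthetic monthly panels with the structure the analysis assumes.

The generator emulates a stationary, seasonally persistent monthly
homicide count series with a weak negative deterministic trend —
SARMA(3,0,0)(1,0,1)_12 noise around level + trend + covariate effects —
together with a skewed low-count execution series (i.i.d. Poisson, about
two per month), a smoothly ramping prison population (in tens of
thousands), and a unit-root (Gaussian random walk) unemployment rate.
Default parameter values sit at the scale of a large U.S. state's monthly
homicide series in the 1990s (mean around 147, innovation SD around 15,
seasonal AR 0.93), so synthetic draws exercise every stage of the pipeline
at realistic signal-to-noise.

All randomness flows through one ``numpy`` Generator seeded from the
config, so a given config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .core import CorrelationProfile, MonthlySeries, acf_pacf, difference

__all__ = [
    "SyntheticConfig",
    "SyntheticPanel",
    "generate_panel",
    "generate_random_walk",
    "overdifferencing_demo",
    "inject_break",
]

_BURN_IN = 600  # months; the seasonal AR near 0.9 needs a long warm-up


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic panel.

    Homicides: level ``mean_level`` (the sample mean of the deterministic
    part; the implied intercept also offsets the covariate means), linear
    trend per month, SARMA(3,0,0)(1,0,1)_12 innovations with the given
    coefficients and innovation SD.  Executions: i.i.d. counts at
    ``execution_rate`` per month.  Prisoners: smooth monotone ramp between
    the start and end levels, in tens of thousands.  Unemployment: Gaussian
    random walk (percent).  ``beta_*`` are the true transfer-function
    effects; ``break_month``/``break_deltas`` optionally shift parameters
    from a given 0-based month onward.
    """

    T: int = 144
    start: tuple[int, int] = (1994, 1)
    mean_level: float = 147.0
    trend: float = 0.096
    ar: tuple[float, float, float] = (0.34, 0.13, 0.32)
    seasonal_ar: float = 0.93
    seasonal_ma: float = -0.76
    innovation_sd: float = 15.0
    execution_rate: float = 2.0
    prisoners_start: float = 6.2322       # tens of thousands
    prisoners_end: float = 15.1925
    unemployment_start: float = 6.0       # percent
    unemployment_sd: float = 0.15
    beta_exec: tuple[float, float] = (-1.31, 0.0)   # contemporaneous, lag 1
    beta_prisoners: float = -8.96
    beta_unemp: float = 1.03              # on first differences of the rate
    break_month: int | None = None
    break_deltas: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.T < 48:
            raise ValueError("T must be at least 48 months")
        if self.innovation_sd <= 0 or self.unemployment_sd <= 0:
            raise ValueError("variance parameters must be positive")
        if abs(self.seasonal_ar) >= 1:
            raise ValueError("|seasonal AR| must be < 1")
        from .arima import _poly_stationary

        if not _poly_stationary(np.asarray(self.ar)):
            raise ValueError("nonseasonal AR polynomial is not stationary")
        if self.execution_rate < 0:
            raise ValueError("execution rate must be nonnegative")

    def to_json(self) -> str:
        d = asdict(self)
        d["start"] = list(d["start"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["start"] = tuple(d["start"])
        d["ar"] = tuple(d["ar"])
        d["beta_exec"] = tuple(d["beta_exec"])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticPanel:
    """Generated series plus the ground-truth record that produced them."""

    homicides: MonthlySeries
    executions: MonthlySeries
    prisoners: MonthlySeries
    unemployment: MonthlySeries
    truth: SyntheticConfig
    n_clipped: int = 0

    def as_dict(self) -> dict[str, MonthlySeries]:
        return {
            "homicides": self.homicides,
            "executions": self.executions,
            "prisoners": self.prisoners,
            "unemployment": self.unemployment,
        }


def _sarma_noise(
    rng: np.random.Generator,
    T: int,
    ar: np.ndarray,
    sar: float,
    sma: float,
    sd: float,
    ar2: np.ndarray | None = None,
    switch_at: int | None = None,
) -> np.ndarray:
    """Simulate SARMA(3,0,0)(1,0,1)_12 noise by recursion with burn-in.

    ``ar2``/``switch_at`` let the nonseasonal AR coefficients change at a
    given post-burn-in month (used by :func:`inject_break`); the innovation
    stream is unaffected by the switch.
    """
    from .dynamics import _full_ar_poly, _full_ma_poly

    a1 = _full_ar_poly(ar, sar)
    m = _full_ma_poly(np.zeros(0), sma)
    a2 = _full_ar_poly(ar2, sar) if ar2 is not None else a1
    n = _BURN_IN + T
    eps = rng.normal(0.0, sd, n)
    u = np.zeros(n)
    switch_abs = None if switch_at is None else _BURN_IN + switch_at
    for t in range(n):
        a = a2 if (switch_abs is not None and t >= switch_abs) else a1
        acc = eps[t]
        for j in range(1, min(t, a.size) + 1):
            acc += a[j - 1] * u[t - j]
        for j in range(1, min(t, m.size) + 1):
            acc += m[j - 1] * eps[t - j]
        u[t] = acc
    return u[_BURN_IN:]


def generate_panel(config: SyntheticConfig) -> SyntheticPanel:
    """Draw one synthetic panel under ``config``.

    Homicides are generated on a continuous scale as

        h_t = c + trend * t + b_e0 e_t + b_e1 e_{t-1} + b_p pris_t
              + b_u (unemp_t - unemp_{t-1}) + u_t,

    with u_t the SARMA noise, then rounded to whole counts and clipped at
    zero (clip events are counted in ``n_clipped``; at the default
    configuration they are vanishingly rare).  The intercept c is chosen so
    the sample mean of the deterministic part equals ``mean_level``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.T
    t = np.arange(1, T + 1, dtype=float)

    execs = rng.poisson(cfg.execution_rate, T).astype(float)
    ramp = (1.0 - np.cos(np.pi * t / T)) / 2.0        # smooth monotone 0..1
    prisoners = cfg.prisoners_start + (cfg.prisoners_end - cfg.prisoners_start) * ramp
    unemp = cfg.unemployment_start + np.cumsum(rng.normal(0.0, cfg.unemployment_sd, T))
    dunemp = np.r_[0.0, np.diff(unemp)]
    exec_lag1 = np.r_[0.0, execs[:-1]]

    deltas = dict(cfg.break_deltas)
    switch_at = cfg.break_month
    ar2 = None
    if switch_at is not None:
        if not 0 < switch_at < T:
            raise ValueError("break month must lie strictly inside the sample")
        if "ar" in deltas:
            ar2 = np.asarray(cfg.ar, float) + np.asarray(deltas["ar"], float)

    u = _sarma_noise(
        rng, T, np.asarray(cfg.ar, float), cfg.seasonal_ar, cfg.seasonal_ma,
        cfg.innovation_sd, ar2=ar2, switch_at=switch_at if ar2 is not None else None,
    )

    b_e0, b_e1 = cfg.beta_exec
    effect = (
        b_e0 * execs
        + b_e1 * exec_lag1
        + cfg.beta_prisoners * prisoners
        + cfg.beta_unemp * dunemp
    )
    intercept = (
        cfg.mean_level
        - cfg.trend * t.mean()
        - float(np.mean(effect))
    )
    h = intercept + cfg.trend * t + effect + u
    if switch_at is not None:
        shift = float(deltas.get("mean_level", 0.0))
        if shift:
            h[switch_at:] += shift
        for lag, key in enumerate(("beta_exec0", "beta_exec1")):
            db = float(deltas.get(key, 0.0))
            if db:
                x = execs if lag == 0 else exec_lag1
                h[switch_at:] += db * x[switch_at:]

    h_rounded = np.round(h)
    n_clipped = int(np.sum(h_rounded < 0))
    h_final = np.clip(h_rounded, 0.0, None)

    mk = lambda name, vals: MonthlySeries(name, cfg.start, vals)
    return SyntheticPanel(
        homicides=mk("homicides", h_final),
        executions=mk("executions", execs),
        prisoners=mk("prisoners", prisoners),
        unemployment=mk("unemployment", unemp),
        truth=cfg,
        n_clipped=n_clipped,
    )


def generate_random_walk(
    T: int,
    drift: float = 0.0,
    sd: float = 1.0,
    seed: int | None = None,
    start: tuple[int, int] = (1994, 1),
    name: str = "random_walk",
) -> MonthlySeries:
    """y_t = drift + y_{t-1} + N(0, sd^2), y_0 = first increment.

    With sd = 0 and drift = 1 this is the exact line 1..T.  This is the
    null process of the augmented Dickey–Fuller test, used for size
    calibration of the battery.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = np.random.default_rng(seed)
    steps = drift + rng.normal(0.0, sd, T) if sd > 0 else np.full(T, drift)
    return MonthlySeries(name, start, np.cumsum(steps))


def overdifferencing_demo(
    T: int = 10_000, seed: int | None = None
) -> tuple[MonthlySeries, CorrelationProfile, CorrelationProfile]:
    """The overdifferencing fingerprint on i.i.d. noise.

    Generates an i.i.d. Gaussian series and returns it with the ACF/PACF
    profiles of (a) its first difference and (b) its first-and-seasonal
    difference.  Differencing a series with no unit root injects a
    non-invertible MA(1): for MA parameter theta the lag-1 autocorrelation
    is -theta/(1+theta^2), equal to -0.5 at theta = 1, so the first
    difference of white noise shows an ACF spike of -0.5 at lag 1 and the
    doubly differenced series a PACF trough near -0.5 at the seasonal lag.
    """
    if T < 200:
        raise ValueError("T must be at least 200 for a stable demonstration")
    rng = np.random.default_rng(seed)
    y = MonthlySeries("iid_noise", (1994, 1), rng.standard_normal(T))
    d1 = difference(y, 1)
    d1_12 = difference(d1, 12)
    max_lag = 36
    return y, acf_pacf(d1, max_lag), acf_pacf(d1_12, max_lag)


def inject_break(panel: SyntheticPanel, month: int, deltas: dict,
                 min_margin: int = 12) -> SyntheticPanel:
    """Regenerate the panel with a parameter shift from ``month`` onward.

    ``deltas`` may contain ``mean_level``, ``beta_exec0``, ``beta_exec1``
    (additive shifts) and ``ar`` (an additive shift to the three
    nonseasonal AR coefficients).  The innovation streams are identical to
    the input panel's, so zero deltas reproduce it bit for bit.
    """
    T = panel.truth.T
    if not min_margin <= month <= T - min_margin:
        raise ValueError(
            f"break month {month} too close to the sample edge "
            f"(need {min_margin} months on each side of 0..{T})"
        )
    cfg = replace(panel.truth, break_month=month, break_deltas=dict(deltas))
    return generate_panel(cfg)
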