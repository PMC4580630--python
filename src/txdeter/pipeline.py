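"""End-to-end orchestration of the re-analysis.

``run`` executes, in order: the unit-root battery on homicides; the
baseline seasonal ARIMA model and its seasonally differenced rival; the
transfer-function models adding executions; impact multipliers and Monte
Carlo impulse responses; the covariate-augmented model with the
likelihood-ratio comparison; and the structural-break models.  A failure
in one stage is recorded in the report and does not abort independent
stages.  Every number in the report is the output of exactly one upstream
operation — the reporter never recomputes.

Model presets
-------------
``eq4``        ARIMA(3,0,0)(1,0,1)_12 + intercept + linear trend
``tf1``        eq4 + Executions_t
``tf2``        tf1 + Executions_{t-1}
``covariate``  tf1 + Prisoners_t (tens of thousands) + first difference of
               the unemployment rate
``breaks_mean``  changing-means break model (intercept only)
``breaks_ar``    intercept + Homicides_{t-1} + Homicides_{t-12}
``breaks_cov``   breaks_ar + year-over-year %change Prisoners_{t-12}
                 + Executions_t + Executions_{t-1}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arima, changepoint, dynamics, unitroot
from .core import (
    MonthlySeries,
    _from_serial,
    difference,
    read_panel_csv,
    write_panel_csv,
)
from .synthetic import SyntheticConfig, generate_panel

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "MODEL_PRESETS",
    "BREAK_PRESETS",
    "load_panel",
    "build_break_design",
    "run",
]

_S = arima.SarimaxSpec
MODEL_PRESETS: dict[str, arima.SarimaxSpec] = {
    "eq4": _S((3, 0, 0), (1, 0, 1)),
    "eq4_seasdiff": _S((3, 0, 0), (1, 1, 1), include_trend=False),
    "tf1": _S((3, 0, 0), (1, 0, 1), exog_terms=(("executions", 0),)),
    "tf2": _S(
        (3, 0, 0), (1, 0, 1),
        exog_terms=(("executions", 0), ("executions", 1)),
    ),
    "covariate": _S(
        (3, 0, 0), (1, 0, 1),
        exog_terms=(("executions", 0), ("prisoners", 0), ("d_unemployment", 0)),
    ),
}

BREAK_PRESETS: dict[str, tuple[str, ...]] = {
    "breaks_mean": ("intercept",),
    "breaks_ar": ("intercept", "homicides[t-1]", "homicides[t-12]"),
    "breaks_cov": (
        "intercept",
        "homicides[t-1]",
        "homicides[t-12]",
        "pct_d12_prisoners[t-12]",
        "executions",
        "executions[t-1]",
    ),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """What to run, on which data, with which settings."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    window: tuple[str, str] | None = None      # YYYY(M) inclusive bounds
    models: tuple[str, ...] = ("eq4", "eq4_seasdiff", "tf1", "tf2", "covariate")
    irf_inputs: tuple[str, ...] = ("executions",)
    irf_models: tuple[str, ...] = ("tf1", "tf2")
    break_models: tuple[str, ...] = ("breaks_mean", "breaks_ar", "breaks_cov")
    horizon: int = 12
    draws: int = 5000
    coverage: float = 0.68
    max_breaks: int = 5
    min_segment: int | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_csv or synthetic")
        unknown = set(self.models) - set(MODEL_PRESETS)
        if unknown:
            raise ValueError(f"unknown model presets: {sorted(unknown)}")
        unknown = set(self.break_models) - set(BREAK_PRESETS)
        if unknown:
            raise ValueError(f"unknown break presets: {sorted(unknown)}")


@dataclass
class AnalysisReport:
    """Structured results of one pipeline run, with provenance."""

    battery: unitroot.BatteryReport | None = None
    fits: dict[str, arima.SarimaxFit] = field(default_factory=dict)
    gates: dict[str, tuple] = field(default_factory=dict)
    multipliers: dict[str, float] = field(default_factory=dict)
    irfs: dict[str, dynamics.ImpulseResponse] = field(default_factory=dict)
    lr: tuple | None = None
    breaks: dict[str, changepoint.BreakFit] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = []
        if self.battery is not None:
            b = self.battery
            lines.append(
                f"battery: d={b.d}, D={b.D}, "
                f"deterministic trend={'yes' if b.include_deterministic_trend else 'no'}"
            )
        for name, f in self.fits.items():
            lines.append(
                f"{name}: sigma2={f.sigma2:.1f} llf={f.llf:.2f} aic={f.aic:.2f} "
                f"R2={arima.r_squared(f):.2f} "
                f"whitenoise={'pass' if self.gates.get(name, (None, False))[1] else 'FAIL'}"
            )
        for key, m in self.multipliers.items():
            lines.append(f"multiplier[{key}] = {m:.2f}")
        for key, irf in self.irfs.items():
            lines.append(
                f"irf[{key}]: 12m cumulative={irf.cumulative[min(11, irf.horizon - 1)]:.2f}, "
                f"band covers zero={irf.covers_zero() if irf.lower is not None else 'n/a'}"
            )
        if self.lr is not None:
            stat, df, p = self.lr
            lines.append(f"LR(covariate vs tf1) = {stat:.1f}, df={df}, p={p:.4f}")
        for name, bf in self.breaks.items():
            dates = bf.break_months() if bf.series_start else bf.breaks
            lines.append(f"{name}: m={bf.m} at {dates}, R2={bf.r2:.3f}")
        for stage, err in self.failures.items():
            lines.append(f"FAILED {stage}: {err}")
        return "\n".join(lines)


def load_panel(path, prisoners_scale: str = "auto") -> dict[str, MonthlySeries]:
    """Read the standard panel CSV and apply the conventional rescaling.

    A ``prisoners`` column holding raw head counts (median above 1000) is
    rescaled to tens of thousands, the unit the covariate model expects;
    pass ``prisoners_scale="none"`` to suppress.  Unemployment is left in
    levels — it is differenced where a model demands it, not at load time.
    """
    panel = read_panel_csv(path)
    if prisoners_scale == "auto" and "prisoners" in panel:
        p = panel["prisoners"]
        if np.median(p.values) > 1000:
            panel["prisoners"] = MonthlySeries("prisoners", p.start, p.values / 1e4)
    return panel


def _lagged(series: MonthlySeries, k: int) -> MonthlySeries:
    return series.lag(k)


def build_break_design(
    panel: dict[str, MonthlySeries], regressors: tuple[str, ...]
) -> tuple[MonthlySeries, pd.DataFrame]:
    """Target and switching-regressor table on the common lagged support.

    Regressor names follow the ``name`` / ``name[t-k]`` convention, plus
    ``intercept`` and ``pct_d12_prisoners[t-k]`` for the year-over-year
    percentage change in prisoners.  Lagged regressors are built before
    trimming; the estimation sample starts where every lag exists.
    """
    hom = panel["homicides"]
    built: dict[str, MonthlySeries] = {}
    for name in regressors:
        if name == "intercept":
            continue
        base, lag = name, 0
        if name.endswith("]") and "[t-" in name:
            base, lag_s = name[:-1].split("[t-")
            lag = int(lag_s)
        if base == "pct_d12_prisoners":
            p = panel["prisoners"]
            pct = 100.0 * (p.values[12:] - p.values[:-12]) / p.values[:-12]
            src = MonthlySeries(base, _from_serial(p.start_serial + 12), pct)
        elif base == "homicides":
            src = hom
        else:
            src = panel[base]
        built[name] = src.lag(lag, name) if lag else MonthlySeries(name, src.start, src.values)

    lo = hom.start_serial
    hi = hom.start_serial + len(hom) - 1
    for s in built.values():
        lo = max(lo, s.start_serial)
        hi = min(hi, s.start_serial + len(s) - 1)
    T = hi - lo + 1
    if T < 24:
        raise ValueError("too few observations after lag construction")
    y = MonthlySeries(
        hom.name,
        _from_serial(lo),
        hom.values[lo - hom.start_serial : lo - hom.start_serial + T],
    )
    cols = {}
    for name in regressors:
        if name == "intercept":
            cols[name] = np.ones(T)
        else:
            s = built[name]
            i0 = lo - s.start_serial
            cols[name] = s.values[i0 : i0 + T]
    return y, pd.DataFrame(cols)


def run(config: AnalysisConfig) -> AnalysisReport:
    """Execute the configured stages; see the module docstring for order."""
    report = AnalysisReport()
    report.provenance = {
        "seed": config.seed,
        "models": list(config.models),
        "draws": config.draws,
        "horizon": config.horizon,
        "coverage": config.coverage,
    }

    if config.input_csv is not None:
        panel = load_panel(config.input_csv)
        report.provenance["input"] = str(config.input_csv)
    else:
        panel = generate_panel(config.synthetic).as_dict()
        report.provenance["input"] = "synthetic"
        report.provenance["synthetic_config"] = json.loads(config.synthetic.to_json())
    if config.window is not None:
        a, b = config.window
        panel = {k: v.window(a, b) for k, v in panel.items()}
        report.provenance["window"] = list(config.window)
    if "unemployment" in panel:
        panel["d_unemployment"] = MonthlySeries(
            "d_unemployment",
            difference(panel["unemployment"], 1).start,
            difference(panel["unemployment"], 1).values,
        )

    hom = panel["homicides"]

    try:
        report.battery = unitroot.battery(hom)
    except Exception as err:  # noqa: BLE001 - stage isolation by design
        report.failures["battery"] = str(err)

    for name in config.models:
        spec = MODEL_PRESETS[name]
        try:
            f = arima.fit(hom, spec, exog=panel, strict=False)
            report.fits[name] = f
            report.gates[name] = arima.residual_gate(f)
        except Exception as err:  # noqa: BLE001
            report.failures[f"fit:{name}"] = str(err)

    for model in config.irf_models:
        f = report.fits.get(model)
        if f is None:
            continue
        for inp in config.irf_inputs:
            try:
                report.multipliers[f"{model}:{inp}"] = dynamics.impact_multiplier(f, inp)
                report.irfs[f"{model}:{inp}"] = dynamics.mc_irf(
                    f,
                    inp,
                    horizon=config.horizon,
                    draws=config.draws,
                    coverage=config.coverage,
                    seed=config.seed,
                )
            except KeyError:
                continue
            except Exception as err:  # noqa: BLE001
                report.failures[f"irf:{model}:{inp}"] = str(err)

    if "tf1" in report.fits and "covariate" in report.fits:
        try:
            restricted, full = report.fits["tf1"], report.fits["covariate"]
            if restricted.nobs != full.nobs:
                # differencing the unemployment covariate shortens the full
                # model's sample; refit the restricted model on it
                hom_common = MonthlySeries(
                    hom.name, full.start, full.endog
                )
                restricted = arima.fit(
                    hom_common, MODEL_PRESETS["tf1"], exog=panel, strict=False
                )
            report.lr = arima.lr_test(restricted, full)
        except Exception as err:  # noqa: BLE001
            report.failures["lr"] = str(err)

    for name in config.break_models:
        regs = BREAK_PRESETS[name]
        try:
            y, Z = build_break_design(panel, regs)
            h = config.min_segment or changepoint.default_min_segment(len(y), len(regs))
            spec = changepoint.BreakSpec(regs, h, config.max_breaks)
            report.breaks[name] = changepoint.select_breaks(y, Z, spec)
        except Exception as err:  # noqa: BLE001
            report.failures[f"breaks:{name}"] = str(err)

    if config.output_dir is not None:
        _write_outputs(config, report, panel)
    return report


def _write_outputs(config: AnalysisConfig, report: AnalysisReport, panel) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.battery is not None:
        report.battery.to_frame().to_csv(out / "battery.csv", index=False)
    if report.fits:
        arima.model_table(report.fits).to_csv(out / "models.csv")
    for key, irf in report.irfs.items():
        irf.to_frame().to_csv(out / f"irf_{key.replace(':', '_')}.csv", index=False)
    for name, bf in report.breaks.items():
        bf.regime_table().to_csv(out / f"{name}.csv")
    series = {k: v for k, v in panel.items() if k != "d_unemployment"}
    try:
        write_panel_csv(out / "panel.csv", series)
    except ValueError:
        pass  # unaligned lagged helpers are not part of the stored panel
    (out / "report.txt").write_text(report.summary() + "\n")
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
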