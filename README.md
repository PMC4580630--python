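# txdeter

Interrupted time-series analysis of whether executions deter homicides,
built as a reusable, tested pipeline.  The package targets the monthly
state-level setting — a homicide count series, a sparse execution count
series, and slow-moving controls (prison population, unemployment) — and
asks the deterrence question the way the modern time-series literature
says it must be asked: pre-test for trends before differencing, model the
seasonal dynamics explicitly, and carry the full parameter *and* residual
uncertainty into the dynamic effect estimates rather than reading a
single coefficient's p-value.

It is aimed at quantitative criminologists and epidemiologists analysing
monthly mortality/intervention count series, and at anyone who needs a
worked, verifiable implementation of this class of analysis.

## What it computes

1. **Unit-root battery** (`txdeter.unitroot`): nine tests — ADF in three
   deterministic variants with the Dickey–Fuller joint Φ statistics, and
   KPSS level/trend at three Bartlett bandwidths — feeding a documented
   rule for the differencing decision (d, D) and the deterministic trend.
   Overdifferencing is diagnosed by its ACF fingerprint: differencing a
   series with no unit root injects an MA(1) whose lag-1 autocorrelation
   is −θ/(1+θ²) = −0.5 at θ = 1.
2. **Seasonal ARIMA transfer functions** (`txdeter.arima`): regression
   with SARMA(3,0,0)(1,0,1)₁₂ errors by exact Gaussian ML,
   y_t = c + τt + Σβ_l x_{t−l} + u_t, with Ljung–Box residual gating at
   lags 1–16, AIC/R², and likelihood-ratio comparison of nested models.
3. **Dynamic effects** (`txdeter.dynamics`): the impact multiplier
   Σβ/(1−Σφ) and Monte Carlo impulse responses — parameters drawn from
   the asymptotic normal, σ² from its scaled inverse χ², innovation noise
   on the shocked path — summarised by pointwise 68% percentile bands or
   likelihood-shape (principal-component) bands.
4. **Structural breaks** (`txdeter.changepoint`): pure structural-change
   regression with m unknown break dates estimated by global SSR
   minimisation (dynamic programming) and m selected by BIC over 0–5.
5. **Synthetic panels** (`txdeter.synthetic`): a generator matching the
   statistical structure above with known truth, so every stage is
   testable without any external data, including null-calibration and
   parameter-recovery studies.
6. **Pipeline + CLI** (`txdeter.pipeline`, `txdeter` console script):
   battery → models → multipliers/IRFs → LR test → changepoints from one
   config, with CSV/JSON outputs.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
panel and write tables under `results/`.  `python analysis/01_simulate_panel.py`
then `python analysis/02_unit_root_battery.py` prints (abbreviated):

```
homicides: mean 130.0, sd 30.2, first-year mean 157.3, last-year mean 95.2
executions: mean 1.98/month (truth 2.0), zero months 17%
...
=> d=0, D=0, deterministic trend included
random-walk control: d=1 (expected 1)
overdifferencing fingerprint: lag-1 ACF of differenced i.i.d. noise = -0.504 (theory -0.5)
```

The battery finds no stochastic trend in the generated homicide series
(so no differencing) but evidence of a deterministic trend, while the
random-walk control is correctly flagged d = 1.  Then
`python analysis/03_transfer_functions.py` fits the model ladder; on this
panel the execution coefficient is −1.19 with standard error 1.00, and
`python analysis/04_impulse_responses.py` turns it into dynamics:

```
impact multiplier (long-run homicides per execution): -3.24
12-month cumulative modal response: -3.05
pointwise 68% band covers zero at every horizon: True
mean band width, pointwise vs shape: 35.1 vs 18.6
band-width inflation from residual-variance uncertainty: x80
```

Read: the point estimate says three fewer homicides per execution in the
long run, but once parameter and residual-variance uncertainty are
simulated through the model, even the 68% band straddles zero at every
horizon — the effect cannot be distinguished from noise, and ignoring
the residual-variance term would understate that uncertainty by nearly
two orders of magnitude.  `python analysis/05_changepoints.py` closes
with the robustness check: BIC-selected structural breaks, and exact
recovery (regime boundary 69, truth 69) of an injected 5σ mean shift.

Library use is three lines:

```python
import txdeter as td
panel = td.generate_panel(td.SyntheticConfig(seed=20240909))
fit = td.fit(panel.homicides, td.MODEL_PRESETS["tf1"], exog=panel.as_dict())
irf = td.mc_irf(fit, "executions", draws=5000, seed=1)
print(irf.impact_multiplier, irf.covers_zero())
```

## Layout

```
src/txdeter/        library (core, unitroot, arima, dynamics,
                    changepoint, synthetic, pipeline, cli)
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md     models, defaults, design decisions, limitations
```
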