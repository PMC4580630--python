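# Methods

`txdeter` re-implements, as a tested pipeline, an interrupted time-series
analysis of monthly homicide counts against execution counts with prison
population and unemployment as controls.  This note records the models,
the numerical choices, and the reasoning behind the decisions that were
genuinely open.

## Unit-root pretesting

Every downstream specification decision rests on whether the homicide
series carries a stochastic trend.  The battery runs nine tests:

* **ADF** regressions of Δy_t on y_{t−1} and lagged differences, in three
  deterministic variants (none; drift; drift + linear trend).  The drift
  and trend variants also report the Dickey–Fuller joint F-type statistics
  (Φ1 for {c, ρ}; Φ2 for {c, τ, ρ}; Φ3 for {τ, ρ}), which is how joint
  drift/trend evidence is read.  τ statistics reject in the left tail, Φ
  in the right.
* **KPSS** statistics η = T⁻² Σ S_t² / s²(ℓ) with the reversed null
  (stationarity around a level or a trend), at three Bartlett bandwidths:
  ℓ = 0, ℓ = ⌊4(T/100)^¼⌋ ("short", 4 at T = 144) and ℓ = ⌊12(T/100)^¼⌋
  ("long", 13 at T = 144).

Augmentation order: AIC over 0..⌊12(T/100)^¼⌋ (Schwert bound), candidates
compared on a common sample and the winner refitted on the longest sample
— the same convention as statsmodels' `adfuller`, against which the τ
statistics are verified to nine significant digits in the tests.

Critical values are embedded tables: the Dickey–Fuller τ and Φ rows for
moderate samples (appropriate for T ≈ 100–500; monthly series of a decade
or three) and the asymptotic KPSS values (0.739/0.463/0.347 level,
0.216/0.146/0.119 trend).

**Decision rule** (deterministic, documented in `battery`): no first
difference (d = 0) if either deterministic-augmented ADF rejects the unit
root at 5% or the long-bandwidth level KPSS fails to reject stationarity;
the linear trend is carried if Φ3 rejects.  Note that Φ3 is a joint test:
it also rejects for a stationary series with no trend, so "trend
included" is a permissive reading — the trend's own t-ratio in the fitted
model is the sharper statement.  There is no formal seasonal unit-root
test in the battery; D = 0 is retained when the fitted seasonal AR
coefficient is inside the unit circle and the seasonally differenced
rival fits worse (higher error variance or serially correlated
residuals), a heuristic implemented in `decide_seasonal_differencing`.

## Why not difference by default: the overdifferencing law

First differencing a series with no unit root injects a non-invertible
MA(1).  For MA parameter θ the lag-1 autocorrelation is −θ/(1+θ²), which
at θ = 1 equals −0.5 (some texts print the denominator as 1+θ; the two
agree at θ = 1, the only case that matters here).  The generator's
`overdifferencing_demo` reproduces the fingerprint by simulation: the
first difference of i.i.d. noise shows a lag-1 ACF of −0.5 (±0.03 at
T = 10,000), and first-plus-seasonal differencing adds a seasonal-lag
artifact.  This is the diagnostic that tells overdifferenced data from
genuinely integrated data.

## Transfer-function models

The maintained model is a regression with seasonal ARMA errors, estimated
by exact Gaussian ML in state-space form (statsmodels SARIMAX):

    y_t = c + τ t + Σ_l β_l x_{t−l} + u_t,
    φ(L) Φ(L¹²) u_t = Θ(L¹²) ε_t,      ε_t ~ N(0, σ²),

with baseline orders (3,0,0)(1,0,1)₁₂.  Parameterisation is
mean-subtraction (regressors enter the observation equation), so the
estimated intercept sits near the detrended sample mean — the convention
of classical intervention-analysis tables; `innovations_intercept`
converts to the innovations-form constant c·φ(1)·Φ(1) when needed.
Deterministic trend is t = 1..T on the estimation sample, not
calendar-anchored; the two differ only in the intercept.

Reported fit statistics: AIC = −2·LLF + 2k with k counting regression,
ARMA **and σ²** (so the baseline model has k = 8); R² = 1 − σ̂²/s²_y with
s²_y the sample variance of the undifferenced target.  Residual adequacy
is gated on Ljung–Box statistics at lags 1..16 with degrees of freedom
reduced by the number of ARMA parameters; the gate passes only if every
defined lag has p > 0.05.  That all-lags rule is deliberately strict —
on a correctly specified model it passes roughly half the time at
T = 144, which is the cost of reading the full lag profile rather than a
single portmanteau value.

Model comparison uses the likelihood ratio 2(LLF_full − LLF_restricted)
with χ² reference; nesting and a common estimation sample are enforced,
and the pipeline refits the restricted model on the full model's sample
when covariate differencing shortens it.

Covariate conventions: prison population enters in tens of thousands
(`load_panel` rescales raw head counts automatically); the unemployment
rate enters in first differences because it carries a unit root — in
levels it would unbalance the regression.

Optimisation: L-BFGS from the statsmodels method-of-moments starting
values (deterministic), with one BFGS retry from the incumbent on
non-convergence; remaining non-convergence raises a diagnostic error
carrying the optimiser trace (or flags the fit when `strict=False`, the
mode used inside Monte Carlo studies).  Non-invertible MA or
non-stationary AR at the optimum attaches a warning, not a failure.

## Impact multipliers and impulse responses

The fitted model is read in its lagged-output form for dynamic
interpretation.  The long-run impact multiplier is Σ_l β_l / (1 − Σ_j φ_j)
with **nonseasonal** AR terms only — the classical convention; the full
long-run gain (also dividing by 1 − Φ) is available behind a switch.  The
modal impulse response is the noise-free recursion of the full
(nonseasonal × seasonal) AR polynomial to a one-month unit pulse in the
input; seasonal dynamics echo in the recursion even though the multiplier
formula excludes them, and for models with no seasonal terms the
cumulative response converges to the multiplier exactly (verified at
H = 240 to 10⁻⁶).

Uncertainty is Monte Carlo (default 5000 draws):

* parameters drawn from the asymptotic normal N(θ̂, V̂); draws whose AR or
  seasonal AR polynomial is non-stationary are rejected and redrawn, with
  the count logged and a hard error if the rejection fraction passes one
  half;
* σ² drawn from its scaled inverse χ² with T − k degrees of freedom;
* innovation noise at the drawn σ applied to the shocked path only (the
  baseline is noise-free), so the band embodies forecast-style
  uncertainty about what one extra execution's aftermath would look like.
  The mechanics of how residual variance should enter the band are a
  genuine design choice; the parameters-only variant sits behind
  `include_residual_uncertainty=False` and produces identical modal paths
  with dramatically narrower bands.

Bands are pointwise equal-tailed percentile intervals, default coverage
0.68 (≈ ±1 SD) — percentiles, not moment-based bands, so asymmetry in the
draw ensemble is preserved.  The likelihood-shape alternative
(`shape_bands`) eigendecomposes the ensemble covariance across horizons
and shifts the modal path along the first principal component scaled by
the 16th/84th percentiles of the draws' scores; under serially correlated
response uncertainty it is tighter than the pointwise band while
preserving the path's shape.  The exact variant of shape band in the
literature is not pinned down; the first-principal-component construction
is adopted and verified against the pointwise band in the degenerate
perfectly-correlated case, where the two coincide.

## Structural breaks

The break model is pure structural change, y_t = z_t' δ_j + u_t over
m + 1 regimes: every listed regressor switches.  (The general formulation
also allows regime-invariant coefficients x_t'β; estimating that partial
case is out of scope, matching how the fitted break models are reported.)
Segment SSRs are precomputed by recursive normal-equation updating
(O(T²p²); a closed-form cumulative-sum path covers the changing-means
model), the optimal partition for each m comes from dynamic programming
with earliest-break tie-breaking, and m ∈ {0..5} is selected by

    BIC(m) = T ln(SSR_m/T) + [ (m+1)p + 1 + m ] ln T,

counting regime coefficients, σ², and — by default — the m break dates
(the convention is genuinely unsettled; `count_break_dates_in_bic=False`
gives the other one).  Minimum segment length defaults to
max(⌈0.15T⌉, p+1), the standard 15% trimming.  Per-regime coefficients
carry segment-wise homoskedastic OLS standard errors and two-sided
t p-values.  Break dates are reported as the last month of the earlier
regime in "YYYY(M)" notation.  The DP is verified against exhaustive
enumeration for T ≤ 40, m ≤ 3.

## Synthetic data: what it emulates, and what it does not

`generate_panel` draws: homicides = intercept + trend·t + covariate
effects + SARMA(3,0,0)(1,0,1)₁₂ noise, rounded to whole counts and
clipped at zero (clip events counted; negligible at the defaults);
executions i.i.d. Poisson at 2/month — skewed, with ~14% zero months;
prisoners a smooth monotone (cosine) ramp from 62,322 to 151,925 heads
(stored in tens of thousands); unemployment a Gaussian random walk
(0.15 pp monthly innovation).  Defaults take the homicide dynamics from
the baseline model's estimates (φ = 0.34, 0.13, 0.32; Φ = 0.93;
Θ = −0.76; σ = 15) and the covariate effects from the covariate model's
(β_exec = −1.31, β_prisoners = −8.96, β_unemp = 1.03, trend +0.096/month).
The trend default follows the covariate model rather than the baseline's
−0.29: the baseline's negative trend is the reduced form of the prisoner
ramp it omits, and carrying both would double-count the decline.  The
intercept is solved so the deterministic part averages `mean_level`
(147), keeping the series on the scale of the real one (≈170 falling to
≈115 across twelve years).  The ramp is deliberately curved so trend and
prisoners remain separately identifiable — in the real data they are
nearly collinear, which is visible here too in the large standard errors
on both.

Null-calibration studies set every covariate effect to zero (and the
trend to the baseline's −0.29), so the fitted execution model matches the
generating process exactly — the clean null for CI-coverage checks.

What the generator does **not** emulate: endogeneity of executions (the
analysis assumes strict exogeneity, as discussed in its limitations);
heteroskedasticity or outliers; any feedback from homicides to the
covariates; calendar effects.  Passing tests on synthetic panels
therefore certify the estimators under the maintained model, not the
substantive conclusions about any real series.

`inject_break` regenerates a panel with parameter shifts (mean level,
execution effects, or nonseasonal AR coefficients) from a chosen month
onward, on identical innovation streams — zero deltas reproduce the panel
bit for bit, making before/after comparisons exact.

## Problem sizes and study conditions

The calibration studies run at the series length the design targets,
T = 144 months: CI coverage of the execution coefficient over 500 null
panels (nominal band 93–97%), parameter recovery over 200 panels at the
covariate-model coefficients (within 2 Monte Carlo SEs), ADF size over
500 random walks (3–7% at the 5% level), KPSS size over 500 stationary
AR(1) draws (≤10%), and break-location recovery over 200 replicates
(median error ≤ 2 months for a 3σ shift).  Impulse-response ensembles use
5000 draws.  The battery's large-sample self-consistency check
(recommending d = 0 with trend on panels drawn from its own stationary
process) runs at T = 600, since at T = 144 the tests' power against the
near-unit seasonal root is genuinely limited — that weakness is a
property of the tests, not of the implementation.

## Known limitations

* ADF/KPSS critical values are fixed moderate-sample tables, not
  response-surface interpolations; outside T ≈ 100–500 they are
  approximate.
* The Φ3-based trend decision is permissive (see above).
* The seasonal-differencing decision is a documented heuristic, not a
  seasonal unit-root test.
* Asymptotic-normal parameter draws near the seasonal unit circle are
  rejected rather than reflected, which slightly truncates the band when
  Φ̂ is within a standard error of 1; the rejection count is reported so
  the truncation is visible.
* Break-date uncertainty (confidence sets for T_j) and sup-F sequential
  testing are not implemented; BIC selection only.
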