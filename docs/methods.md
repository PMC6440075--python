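# Methods

This document records the statistical model, the synthetic data-generating
process, the numerical choices, and the open design decisions behind
`tempmort`.

## 1. Regression model

Daily death counts are modelled by quasi-Poisson regression:

```
log E(Y_t) = alpha + DOW_t + HOL_t (+ POP_t) + ns(day_t; df) + cb(x_t ... x_{t-L})
Var(Y_t)   = phi * E(Y_t)
```

* `DOW`: treatment-coded weekday contrasts (6 columns, first level as
  baseline).
* `HOL`: holiday indicator (dropped with a warning if constant over the
  fitted rows).
* `POP`: standardised population, included only when it varies.
* `ns(day)`: a natural cubic spline of the day index capturing the
  long-term and seasonal trend, with `df = round(df_per_year * span/365.25)`
  and `df_per_year ∈ {7, 8, 9}`.
* `cb`: the DLNM cross-basis over lags 0–30 (below).

The first `lag_max` rows (incomplete lag history) are dropped, not imputed.
Seasonal analyses (winter = Dec–Mar, summer = Jun–Sep) restrict *outcome*
rows to the season's months after computing lagged exposures from the full
continuous series, so early-January rows draw lags from December.

### Cross-basis

The exposure basis `R(x)` is linear or a quadratic B-spline without
intercept (first constrained column dropped), **centred** so that
`R(x_ref) = 0`; the lag basis `C(l)` is constant or a quadratic B-spline
*with* intercept, evaluated at integer lags. The cross-basis entry for day
`t` and column `(j, k)` is `sum_l R_j(x_{t-l}) C_k(l)`. Centring the
exposure side (not the lag side) makes the tensor product identifiable next
to the model intercept and anchors all relative risks at `x_ref`.

Knot placement: exposure knots at equal distances over the observed
temperature range (mid-range for one knot, thirds for two); lag knots at
equal distances on the raw 0–30 scale (15, or {10, 20}). The reference
temperature defaults to the training-period median and is configurable.

### Fitting

IRLS with log link: weights `mu`, working response `eta + (y - mu)/mu`,
convergence when the relative deviance change is below 1e-8 (at most 100
iterations, else a `ConvergenceError` carrying the deviance trace). Rank
deficiency is detected up front by pivoted QR and reported with the
offending column names. The dispersion is the Pearson estimate
`phi = chi^2/(n - p)` and the coefficient covariance is
`phi * (X'WX)^{-1}`. The fitter is cross-checked in the test suite against
`statsmodels.GLM(..., Poisson).fit(scale="X2")` to 1e-6.

### Model selection

The candidate grid crosses 4 exposure shapes (linear; quadratic B-spline
with 0, 1, 2 interior knots) × 4 lag shapes (constant; quadratic B-spline
with 0, 1, 2 knots) × 3 trend resolutions (7, 8, 9 df/year) = 48 models
with cross-basis dimension 1–20. Models are ranked by
`QAIC = -2 loglik / phi_ref + 2k`, where `phi_ref` is the dispersion of the
most complex candidate (a common denominator, so the penalty comparison is
fair) and `loglik` the Poisson log-likelihood at the quasi-likelihood
estimate. Candidates whose fit fails are excluded from the ranking.

### Prediction

For temperature `x`, the cumulative contrast `w_{jk}(x) = R_j(x) sum_l
C_k(l)` gives the overall cumulative log-RR `w'beta` with delta-method
variance `w'Vw`; lag-specific contrasts use `R_j(x) C_k(l)` per lag.
Intervals are Wald: `exp(w'beta ± 1.96 sqrt(w'Vw))`. The RR surface is the
lag-specific RR evaluated over a temperature × lag grid, exactly 1 along
the reference temperature row.

## 2. Synthetic data generator

`TruthScenario` defines the study conditions; defaults are the conditions
under which all headline numbers are produced.

* **Temperature**: seasonal sinusoid (mean 16 °C, amplitude 6 °C, peak at
  day-of-year 196) plus an AR(1) anomaly (`rho = 0.7`) with *marginal* SD 3
  °C (innovation SD scaled by `sqrt(1 - rho^2)`); `tmin`/`tmax` are the
  daily mean ± a diurnal half-range. Rejects `|rho| >= 1`.
* **Truth surface**: separable, `f(x) * w(l)`. The exposure response
  `f` is piecewise quadratic: zero with zero slope at the reference
  temperature, rising to `cold_log_rr = 0.5` at the cold anchor
  (mean − amplitude − 2 SD) and `heat_log_rr = 0` at the symmetric heat
  anchor — a C1 curve with the cold-dominated shape typical of European
  series. Lag weights `w(l)` decay exponentially (scale 4 days) and sum to
  1, so the true overall cumulative curve equals `f` exactly.
* **Mortality**: `log mu_t = log 20 + DOW + holiday + seasonal cosine
  (amplitude 0.08, peak mid-January) + sum_l w_l f(x_{t-l})`; counts are
  Poisson–gamma with `Var = phi * mu` (`phi = 1.3`), i.e. NB1-type
  overdispersion. The first 30 days have `deaths = NaN` so no synthetic
  series ever exposes an incomplete lag history.
* **Distorted twin** (`distort_temperature`): `scale * x + shift` plus an
  upper-tail quadratic distortion above the 90th percentile and optional
  noise; the daily adjustment is computed from `tmean` and added
  identically to `tmin`/`tmax` so `tmin <= tmean <= tmax` is preserved.

## 3. Bias correction

Empirical quantile mapping at probabilities `(1..n)/(n+1)` (default
`n = 99`). Corrected values interpolate linearly between matched
quantiles; ties in the simulated quantiles (flat spells) are collapsed to
their mean target. Beyond the outermost quantiles the default rule is a
constant offset (the correction at the nearest fitted quantile), avoiding
wild extrapolation of extremes; linear extrapolation of the end slopes is
available. Maps are fitted per season (winter/summer/other) by default.
When a data frame is corrected, companion temperature columns receive the
same per-day delta as the mapped column (ordering preserved).

## 4. Validation

* **Effect validation**: the lag-specific log-RR vectors at the training
  1st/50th/99th-percentile temperatures, lags 0–30, estimated on the
  training and test periods (sharing one cross-basis spec), compared by
  relative RMSE and relative mean absolute deviation, both scaled by the
  *mean test-period effect*. Because that mean is near zero by
  construction, the relative metrics are large and mostly useful
  comparatively; they are flagged `undefined` (not infinite) when the mean
  is exactly ~0.
* **Prediction bootstrap**: test-period days resampled i.i.d. with
  replacement (50 replicates by default); the training-fit predictions are
  scored against each resample by RMSE, and the per-replicate relative bias
  `(mean predicted - mean observed)/mean observed` is summarised as a
  histogram with mean and SD. Training coefficients are reused — the model
  is not refitted per resample.
* **Out-of-period trend**: the fitted trend spline's natural linear
  extension tracks the seasonal slope at the training boundary and explodes
  when extrapolated months ahead. Day indices beyond the fitted range are
  therefore folded back by whole (365.25-day) years, continuing the last
  observed seasonal cycle. This keeps out-of-period predictions nearly
  unbiased (|mean relative bias| ≈ 0.002 on a 700-day synthetic test
  period) at the cost of ignoring any secular trend beyond the training
  window.

## 5. Simulation study

A generative truth is placed *inside* the default model space: on a fresh
synthetic covariate history, the true coefficient vector of the default
design is set from the scenario — baseline/weekday/holiday directly, the
seasonal cosine by least squares onto the trend spline, and the separable
truth surface by factorised least squares onto the cross-basis (exposure
side and lag side solved separately; coefficients are their outer
product). The matching scenario is therefore *exactly* correctly
specified, which is what makes ≈ 95% coverage the right expectation rather
than an approximation.

Each of `m = 500` replicates regenerates counts from the truth mean with
NB1 overdispersion, refits each candidate parameterisation, and extracts
the overall cumulative log-RR at the 1st-percentile temperature with its
delta-method variance. Reported per scenario:

* percent bias  `|mean(b̂ - b)| / mean(b) * 100`
* coverage      `mean( |b̂ - b| <= 1.96 sqrt(V) )`
* percent RMSE  `sqrt(mean((b̂ - b)^2)) / mean(b) * 100`

Replicates whose fit fails are excluded; a scenario losing more than 10% of
replicates is flagged unreliable. Under-flexible scenarios (linear
exposure, constant lag) show degraded coverage and inflated RMSE.

## 6. Numerical choices

* B-spline evaluation via `scipy.interpolate.BSpline.design_matrix`
  (Cox–de Boor); a hand-coded recursion serves as the test oracle.
* The natural cubic spline is a deterministic constrained B-spline
  (zero second derivative at the boundary, first constrained column
  dropped, linear extension outside the boundary), matching R's
  `splines::ns` — fitted values were verified against R and frozen as a
  regression oracle. A quantile-based `cr`-style basis was rejected
  because it spans the constant and is collinear with the intercept.
* `z = 1.959963984540054` (the exact normal 97.5% point) everywhere.
* Linear predictors are clipped at ±30 before exponentiation.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic artefact records its seed, and pipeline reruns from the same
  configuration are byte-identical.

## 7. Open design decisions

* The relative-metric denominator for effect validation is read as the
  *mean* test effect `sum(beta)/n` (the printed form is ambiguous); this
  matches the analogous denominators of the simulation-study formulas.
* Candidate model numbering follows (lag shape, exposure shape, trend df)
  order; ids 1–12 are the constant-lag models.
* Day-level i.i.d. resampling is used for the prediction bootstrap; a block
  bootstrap would respect autocorrelation and is noted as future work.
* Whether validation predictions should refit or reuse training
  coefficients is ambiguous in the underlying method description;
  coefficients are reused.

## 8. Limitations

* The generator's truth surface is separable (`f(x) w(l)`); non-separable
  exposure–lag interactions are not simulated.
* NB1 (Poisson–gamma) noise matches the quasi-Poisson variance assumption
  by construction; model misspecification of the variance function is not
  explored.
* The trend-folding rule for out-of-period prediction ignores secular
  mortality trends beyond the training window.
* Quantile mapping is univariate and per-season; it does not correct
  temporal autocorrelation or multi-variable dependence.
* No penalised DLNM extensions, threshold models, or natural-spline
  exposure functions beyond the candidate grid.
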