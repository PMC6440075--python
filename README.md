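# tempmort

Temperature–mortality association analysis with distributed lag non-linear
models (DLNMs), built as a self-contained, fully testable pipeline:

1. **Synthetic data** — daily death counts and temperatures generated from a
   known exposure–lag–response truth, so every downstream estimate can be
   checked against the quantity that produced the data.
2. **Bias correction** — empirical quantile mapping of a systematically
   distorted ("climate model") temperature series onto the observed one,
   fitted per season.
3. **Cross-basis construction** — the DLNM tensor-product basis encoding a
   non-linear exposure response distributed over lags 0–30 days.
4. **Fitting and model selection** — quasi-Poisson regression by IRLS over a
   grid of 48 candidate spline parameterisations, ranked by QAIC.
5. **Prediction** — cumulative and lag-specific relative risks with
   delta-method Wald intervals, plus the full exposure–lag RR surface.
6. **Validation** — train/test comparison of effect estimates and a
   day-resampling bootstrap of prediction error.
7. **Simulation study** — a parametric bootstrap measuring percent bias,
   95%-interval coverage and percent RMSE of the overall cumulative effect
   under correct and under-flexible specifications.

## The model

For daily deaths $Y_t$ and mean temperature $x_t$,

$$\log E(Y_t) = \alpha + \mathrm{DOW}_t + \mathrm{HOL}_t
  + ns(t;\ 7\text{–}9\ \mathrm{df/yr}) + cb(x_t, \ldots, x_{t-30})$$

with $\mathrm{Var}(Y_t) = \phi\, E(Y_t)$ (quasi-Poisson). The cross-basis
$cb$ is the tensor product of a centred exposure basis $R(x)$ (linear or
quadratic B-spline, $R(x_{\mathrm{ref}}) = 0$) and a lag basis $C(\ell)$
(constant or quadratic B-spline with intercept):

$$cb_{t,\,jv_\ell+k} = \sum_{\ell=0}^{30} R_j(x_{t-\ell})\, C_k(\ell).$$

The default parameterisation uses quadratic B-splines with one exposure knot
(mid-range) and one lag knot (at 15), i.e. a 3 × 4 = 12-column cross-basis.
The overall cumulative log-RR at temperature $x$ versus the reference is
$w(x)^\top \beta_{cb}$ with $w_{jk}(x) = R_j(x) \sum_\ell C_k(\ell)$, and its
delta-method standard error is $\sqrt{w^\top V w}$.

## Worked example

```python
import numpy as np
from tempmort import (TruthScenario, generate_region, fit_model, ModelSpec,
                      predict_cumulative)

scenario = TruthScenario(n_days=5478, seed=0)   # 15 years, known truth
region = generate_region(scenario)
fit = fit_model(region, ModelSpec(), reference_temp=scenario.reference_temp)
print(fit.dispersion)                            # 1.276 (truth: 1.3)

pct = fit.design.temp_percentiles                # {1: 5.1, 50: 16.0, 99: 26.7}
curve = predict_cumulative(fit, temp_grid=np.array([pct[1], pct[99]]))
```

Output for this seed: the cumulative relative risk over lags 0–30 at the
1st-percentile temperature (5.1 °C) is **1.46 (95% CI 1.25–1.70)** versus
the reference, and **0.92 (0.75–1.12)** at the 99th percentile (26.7 °C) —
recovering the generator's cold-dominated truth
(`TruthScenario` default: cumulative log-RR 0.5 at the cold anchor, 0 at
the heat anchor).

## Command line

```bash
tempmort simulate-data --n-days 5478 --seed 0 --out observed.csv --distorted-out sim.csv
tempmort bias-correct --observed observed.csv --simulated sim.csv --out corrected.csv
tempmort select  --data observed.csv --out ranking.csv     # 48-model QAIC grid
tempmort predict --data observed.csv --outdir out/         # RR curves + surface
tempmort validate --train train.csv --test test.csv --out validation.json
tempmort simstudy --m 500 --n-s 2000 --seed 0 --out simulation.csv
tempmort all --config run.yaml                             # full pipeline
```

`tempmort all` writes every artefact (corrected series, model ranking,
RR curves/surface, validation report, simulation table, `summary.json`)
under the configured output directory; reruns from the same configuration
are byte-identical.

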