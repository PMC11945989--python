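# casim

Constrained, additive single-index modelling of **cumulative air-pollution
and weather effects** on a daily health-outcome count series.

Epidemiological time-series studies often ask not just *whether* an exposure
(SO₂, PM10, NOₓ, NO₂, O₃, temperature, humidity) affects daily respiratory
hospital admissions, but over *how many days* the exposure accumulates and
with what weights. `casim` implements a semiparametric model that answers
both questions while handling the day-of-week admission pattern and a
sustained level shift after an excluded epidemic period.

## The model

For daily counts `Y_t` the model on the log scale is

    ln Y_t = μ + λ(t) + S(t) + Σ_j g_j(θ_jᵀ X_j,t) + ε_t

- `μ` — baseline log admissions on the default day (Friday) with zero
  cumulative effects.
- `S(t) = Σ_k α_k D_k,t` — day-of-week effect, exactly zero on the default
  day.
- `λ(t)` — four-parameter logistic growth curve: zero before an excluded
  intervention window, `ξ1 + ξ3 / (1 + exp(−ξ2(τ − ξ4)))` for τ days after
  its end. It captures a lasting behavioural shift (e.g. after the 2003
  SARS epidemic).
- `g_j(θ_jᵀ X_j,t)` — one **single-index block per covariate**:
  `X_j,t = (X_j,t, …, X_j,t−L_j)` is the lag window, the weights θ_j live on
  the *ordered simplex* (non-negative, non-increasing in lag, summing to
  one), and `g_j` is an unknown smooth curve — constrained to be
  non-decreasing for pollutant-like covariates.

Estimation: the index is mapped to [0, 1] with a rescaled centred Beta CDF
(scale = 95th percentile of the lag-window sup norms), `g_j` is a cubic
B-spline on quantile-placed interior knots (N = max(n^{1/5.5}, 5)) fitted by
restricted least squares (non-decreasing coefficients when required), θ_j by
gradient projection onto the ordered simplex, and all components by
backfitting. Lag lengths L_j are chosen by AIC = log MSE + 2m/n via a
common-lag grid scan followed by coordinate refinement; uncertainty comes
from a residual bootstrap with percentile bounds.

## Worked example

```python
import numpy as np
from casim import backfit, bootstrap_fit, confidence_bounds, default_truth, simulate_dataset

truth = default_truth(n=1500, noise_sd=0.05, seed=1)   # 2 pollutant-like + 1 weather-like series
dataset, components = simulate_dataset(truth)

fit = backfit(dataset, truth.lags, monotone=truth.monotone)
print(f"converged={fit.converged}  n_used={fit.n_used}  mse={fit.mse:.5f}  aic={fit.aic:.3f}")
print("alpha:", np.round(fit.weekly.alpha, 3))
print("theta[pm]:", np.round(fit.weights[0].theta, 3))
```

prints

```
converged=True  n_used=1382  mse=0.00303  aic=-5.763
alpha: [0.07  0.093 0.239 0.161 0.175 0.2  ]
theta[pm]: [0.502 0.174 0.104 0.104 0.051 0.051 0.013]
```

`n_used` counts the days whose lag history stays clear of the series start
and the excluded window; `mse` is the mean squared log-scale residual
(noise was generated at sd 0.05, so ≈ 0.0025 plus approximation error); the
weekly effects and the non-increasing lag weights are close to the
generating values (α = 0.07…0.24, θ geometric with ratio 0.6).

The same pipeline is scriptable from the shell:

```bash
casim simulate --n 1500 --seed 1 --out data.csv --truth-out truth.yaml
casim fit data.csv --config config.yaml --lags 6,4,3 --outdir results/
casim select-lags data.csv --config config.yaml -l 10 -K 200 -d 5
casim bootstrap data.csv --config config.yaml --lags 6,4,3 -B 500
```

There is also a scikit-learn-style front end, `casim.CasimRegressor`, with
`fit(X, y)` / `predict(X)` on a date-indexed covariate DataFrame, usable in
sklearn pipelines and model selection.

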