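# ssivcar

Spatial autoregressive modelling with **heterogeneous** spatial
autocorrelation: a Python library for the spatial single-index
varying-coefficient autoregressive (SSIVCAR) model, its spline + two-stage
least squares estimator, synthetic data generators, a homogeneous-SAR
baseline, and spatial-dependence diagnostics.

## The problem

The classical spatial lag (SAR) model

> Y = ρWY + Xβ + ε

forces every spatial unit to share one autocorrelation coefficient ρ. In
regional data — pollution spillovers, economic interactions — the strength of
dependence varies with unit characteristics, and fitting a constant-ρ model
to such data badly biases β and grossly inflates the error-variance estimate
(see `examples/sar_misspecification.py`).

The SSIVCAR model replaces ρ with a smooth function of a scalar index of
unit-level variables u ∈ ℝᵐ:

> yᵢ = g(uᵢᵀα) Σⱼ wᵢⱼ yⱼ + xᵢᵀβ + εᵢ,  ‖α‖ = 1, α₁ ≥ 0,

so the spatial autocorrelation strength g(uᵢᵀα) changes across units while
the single-index structure keeps estimation tractable in m. The unknown g is
approximated by a truncated power spline B(t)ᵀδ with data-driven knots; the
index direction α is estimated by minimizing a profile least-squares
criterion with a trust-region method over the omit-one-component
parameterization α = (√(1−‖ϕ‖²), ϕ); and (δ, β) are estimated by two-stage
least squares, instrumenting the endogenous spatial lag WY with
[X, WX, W²X, WU, W²U] plus spline-interacted and model-implied-mean columns
that track E[WY | X, U]. See `docs/methods.md` for the full procedure and
its design decisions.

The package targets researchers in spatial econometrics and spatial
epidemiology who want unit-varying spillover strength with an interpretable
index, plus the Monte Carlo tooling to validate the estimator on synthetic
designs.

## Worked example

```python
import numpy as np
import ssivcar as sv

design = sv.SimulationDesign()     # 15×15 grid, Rook weights, n = 225,
                                   # α = (1/2, √3/2), β = (1, 2), g = sin
data = sv.simulate(design, seed=3)
fit = sv.fit(data)
print(np.round(fit.alpha, 4), np.round(fit.beta, 4), round(fit.sigma2, 4))
```

prints

```
[0.4856 0.8742] [0.9924 2.3485] 1.3031
```

— the index direction (truth (0.5, 0.866)) is recovered to a few hundredths
from a single draw of 225 units; the regression coefficients (truth (1, 2))
and the residual variance (truth 1) scatter more, with single-draw standard
errors around 0.15–0.3. Averaged over replications the estimates concentrate
on the truth:

```python
result = sv.run_experiment(design, nmc=25, base_seed=0)
print(result.table.round(4))
```

```
parameter  true_value  estimate     se   bias    mse
   alpha1       0.500    0.4929 0.0515 0.0071 0.0027
   alpha2       0.866    0.8681 0.0289 0.0020 0.0008
    beta1       1.000    0.9851 0.1205 0.0149 0.0147
    beta2       2.000    1.9965 0.1507 0.0035 0.0227
   sigma2       1.000    1.0436 0.1226 0.0436 0.0169
```

Each `examples/*.py` script demonstrates one capability: weight-matrix
construction, simulation + fitting, Monte Carlo studies, the homogeneous-SAR
misspecification experiment, the Moran/LM diagnostic battery, and an
empirical-style workflow on a 295-unit irregular region.

A thin CLI mirrors the library for shell use:

```bash
ssivcar weights --kind rook --h 15 --out W.mtx
ssivcar simulate --seed 7 --out data.csv
ssivcar fit --data data.csv --weights W.mtx --out fit.json
ssivcar diagnose --data data.csv --weights W.mtx --perms 999 --seed 1
```

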