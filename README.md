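# kuznefit

Fitting, identifiability analysis and forecasting for the simplified
Kuznetsov tumor–immune model on per-patient lesion time series.

## What it is for

Solid-tumor trials record the longest diameter (LD) of a target lesion at
sparse clinic visits. Simple growth laws cannot reproduce the relapse and
"U"-shaped response patterns seen under immunotherapy, because those
patterns arise from the interplay between tumor cells (TC) and cytotoxic
effector cells (EC: CTL and NK cells). `kuznefit` fits a mechanistic
model of that interplay to each patient's trajectory, asks how well the
fitted parameters are actually determined by the data, and tests whether
the fitted dynamics forecast the next visits.

The model is a quasi-steady-state reduction of Kuznetsov's EC–TC
kinetics, nondimensionalized with cell-number scales E₀ = 10⁷ and
T₀ = 10⁹:

    dx/dτ = σ + ρxy/(η + y) − δx − μxy
    dy/dτ = αy − (E₀/T₀)·xy

where x = E/E₀, y = T/T₀, and σ, ρ, η, μ, δ, α are dimensionless rates
(effector influx, stimulated recruitment, recruitment saturation,
effector inactivation, effector death, tumor growth). Per patient, the
six parameters and the initial effector level x₁ are estimated by
bound-constrained nonlinear least squares with a multistart global
search; y₁ comes from the first measurement.

On top of the fit the package provides:

- **Global practical identifiability** — the smallest axis-aligned box
  containing all parameter vectors whose predictions stay within ε (20%)
  of the optimal fit at every visit; wide boxes flag parameters the data
  do not pin down.
- **Held-out forecasting** — refit without the last ζ visits (2 or 3),
  extrapolate, and score the held-out points with MAPE.
- **Extreme-case envelopes** — trajectories maximizing/minimizing the
  terminal prediction while staying within θ (10%) of the truncated fit
  over the fitted window: the honest worst-case band around a forecast.
- **Synthetic cohorts** — virtual patients with clinic-style visit
  schedules, model-generated trajectories and 1 mm LD measurement noise,
  with ground truth retained for recovery testing.

## Worked example

```python
import numpy as np
from kuznefit import (FitConfig, ScaleConstants, SyntheticSpec,
                      generate_cohort, fit_patient)
from kuznefit.identifiability import IdentConfig, parameter_box

scales = ScaleConstants()
cohort, truths = generate_cohort(
    SyntheticSpec(n_patients=1, ld_noise_sd=0.0, seed=42, n_visits=(9, 9)),
    scales,
)
rec = cohort.records[0]
fit = fit_patient(rec, FitConfig(n_starts=3, max_evals=20_000, seed=1,
                                 target_objective=1e-9), scales)
print(f"SSR = {fit.objective:.2e}, R^2 = {fit.metrics.r2:.5f}")
box = parameter_box(rec, fit, IdentConfig(epsilon=0.20, max_evals=2000, seed=3),
                    FitConfig(), scales)
print("alpha in [%.3f, %.3f] (fit %.3f)" % (box.pmin[5], box.pmax[5], fit.params.alpha))
```

Output:

```
SSR = 1.42e-08, R^2 = 1.00000
alpha in [0.030, 0.805] (fit 0.099)
```

The virtual patient's 9-visit trajectory is reproduced essentially
exactly (sum of squared residuals ~10⁻⁸ on normalized burden, R² = 1.0).
The identifiability box for α spans more than a decade around the fitted
value: many growth rates are compatible with this trajectory at the 20%
deviation tolerance — a typical finding, and the reason trajectory
recovery rather than parameter recovery is the meaningful target.

The same analysis runs end to end from the shell:

```bash
kuznefit simulate --n-patients 5 --seed 1 --out synthetic
kuznefit report --data synthetic/cohort.csv --out results --seed 1
```

writing per-patient fits (`fits.csv`, `fits.json`), box edges
(`boxes.csv`), range-frequency curves, forecasts with envelope terminals
(`predictions.csv`, `trajectories.csv`) and grouped summaries
(`summary.csv`).

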