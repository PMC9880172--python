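# toripk

Population pharmacokinetics and exposure-response tooling for the
flat-dose question in anti-PD-1 antibody therapy: is a fixed 240 mg every
3 weeks (Q3W) regimen pharmacologically interchangeable with weight-based
3 mg/kg every 2 weeks (Q2W)?

The package implements, end to end and on synthetic data:

- the **final population-PK model** of toripalimab — a two-compartment
  IV-infusion model whose clearance changes over treatment time following
  a sigmoidal-Emax function,

  CL(t) = CL_base · exp( Emax · t^γ / (T50^γ + t^γ) ),

  with Emax = −0.444 (so CL drifts to exp(−0.444) ≈ 0.64 of baseline),
  T50 = 1,580 h and γ = 1.32, plus multiplicative covariate effects on CL
  (body weight, albumin, LDH, creatinine clearance, sex, anti-drug-antibody
  status) and V1 (body weight, race);
- **exposure simulation and regimen comparison**: first-dose and
  steady-state AUC/Cavg/Cmax/Ctrough, paired geometric-mean ratios with
  90% CIs, percentile-band coverage, and forest-plot covariate effects
  against the 0.80–1.25 clinical-relevance band;
- **estimation machinery**: per-subject empirical-Bayes (MAP) estimates,
  a Laplace-approximation population fit, stepwise covariate search
  (forward ΔOFV ≥ 6.63, backward ≥ 10.83), nonparametric bootstrap, and a
  prediction-corrected visual predictive check (pcVPC);
- **exposure-response analysis**: logistic safety/efficacy models with
  AIC backward elimination that always retains the exposure term,
  Kaplan-Meier / log-rank analysis of PFS by exposure quartile, and Cox
  proportional-hazards forest tables;
- **synthetic data generators** for the covariate population (weight
  median 63.5 kg, p5/p95 = 46.6/89.4 kg), NONMEM-style PK datasets, and a
  two-arm trial with configurable exposure-response truth.

It is aimed at pharmacometricians and methods-minded biostatisticians who
want a transparent, test-covered re-implementation of this class of
model-informed drug development (MIDD) analysis without NONMEM.

## Worked example

```python
import numpy as np
from toripk.model_core import (CovariateProfile, FixedEffects,
                               individual_parameters, steady_state_clearance,
                               covariate_multiplier_cl, covariate_multiplier_v1)
from toripk.exposure import first_dose_exposure, steady_state_exposure
from toripk.simulate import DosingRegimen

theta = FixedEffects()                       # published final-model estimates
ref = individual_parameters(theta, CovariateProfile())   # typical patient

print(round(steady_state_clearance(ref), 2))             # 9.56  (mL/h)
reg = DosingRegimen(flat_mg=240, interval=504, n_doses=1)
ss = steady_state_exposure(ref, reg)
print(round(ss.auc_tau), round(ss.cavg, 1))              # 25110 49.8
d1 = first_dose_exposure(ref, reg)
print(round(d1.auc_tau), round(d1.cavg, 1))              # 13187 26.2

for w in (46.6, 89.4):
    p = CovariateProfile(weight=w)
    print(w, round(covariate_multiplier_cl(p, theta), 2),
             round(covariate_multiplier_v1(p, theta), 2))
# 46.6 0.97 0.86
# 89.4 1.03 1.18
```

The typical patient's steady-state clearance is 9.56 mL/h (baseline
14.9 mL/h times the 0.64 long-term factor), giving a steady-state AUC over
the 504-h interval of 240,000 µg / 9.56 mL/h ≈ 25,110 h·µg/mL and an
average concentration of 49.8 µg/mL — far above the ~3 µg/mL receptor-
saturation threshold. The weight effects at the population 5th and 95th
percentiles (0.97/1.03 on CL, 0.86/1.18 on V1) all sit inside the
0.80–1.25 band, the quantitative argument that weight-based dosing is not
needed.

A shell pipeline is available as `toripk`:

```bash
toripk synth table3 --out t3.csv
toripk er-logistic --table t3.csv --endpoint ae_grade3 --out er.json
toripk compare --n 200 --seed 1 --out-dir cmp/
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline covariate-effect ratios
from the final model — the multiplicative effect of 46.6 kg and 89.4 kg
body weight on CL and V1 relative to the reference patient — by running
the package's forest-effect machinery and writing one JSON object:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/toripk/model_core.py` — model constants, time-varying CL, covariate
  sub-models, forest effects (`data/final_model.yaml` holds the constants)
- `src/toripk/simulate.py` — dosing events, batched ODE solver, population
  simulation, residual error
- `src/toripk/exposure.py` — interval metrics, steady state, GMR/coverage
- `src/toripk/estimation.py` — empirical Bayes, Laplace fit, SCM,
  bootstrap, pcVPC
- `src/toripk/exposure_response.py` — logistic E-R, KM/log-rank, Cox
- `src/toripk/synthetic_data.py` — population/trial generators and the
  deterministic safety-table fixture
- `src/toripk/io.py`, `src/toripk/cli.py` — NONMEM-style CSV I/O and CLI
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
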