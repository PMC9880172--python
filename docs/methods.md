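# Methods

## Structural PK model

Serum concentrations follow a linear two-compartment disposition model
with zero-order IV infusion. Amounts are in mg, volumes in mL, time in
hours; concentrations are reported in µg/mL (A1/V1 in mg/mL × 10³). The
single nonlinearity is a slow, deterministic drift of clearance with time
after the first dose,

    CL(t) = CL_base · exp( Emax_i · t^γ / (T50^γ + t^γ) ),

the sigmoidal-Emax time model used for several anti-PD-1 antibodies:
clearance falls (for Emax_i < 0) from CL_base toward CL_base·exp(Emax_i)
with half the log-scale change reached at T50. Time is continuous across
doses — the drift does not reset at later doses, which is the only
sensible reading given T50 ≈ 1,580 h versus dosing intervals of 336–504 h.
Whether the original analysis integrated the drift continuously within the
ODE or stepwise per interval is not documented; continuous integration was
chosen here and matters little at these time scales.

Default parameter values (packaged in `data/final_model.yaml`): Emax_TV =
−0.444, T50 = 1,580 h, γ = 1.32, CL_TV = 14.9 mL/h, V1_TV = 3,710 mL,
Q = 36.5 mL/h, V2 = 796 mL.

## Covariate sub-models

Continuous covariates enter as power terms scaled to the population
reference value (weight 64 kg, albumin 43.7 g/L, LDH 199 U/L, CRCL
94.31 mL/min); categorical covariates as (1 + θ) factors relative to the
reference category (male, Asian, ADA-negative). The (1 + θ) reading is
deliberate: a bare multiplicative θ of 0.191 for ADA-positivity would
imply an implausible 81% clearance reduction, whereas the documented
categorical structure P = θ_k·(1 + θ_j·X) gives the intended +19.1%. A
second reference preset (63.5 kg / 43.6 / 198 / 94.3) reproduces the
published forest-plot reference patient; both presets give the printed
weight ratios at two decimals.

Forest-plot uncertainty: when no bootstrap replicate set is available,
parameter draws are independent normals on the estimation scale (log-normal
for strictly positive structural parameters) with SDs from the printed
%RSE values. This ignores estimation correlations and is documented as an
approximation; the 0.80–1.25 clinical-relevance band is applied to the
median ratio.

## Random effects and residual error

Between-subject variability applies to Emax (additive), CL and V1
(log-normal). Published %CVs (39/31/27%) are converted to variances by
ω² = ln(1 + CV²) — all three land inside the published variance-scale CIs,
as does the CL–V1 covariance implied by the 0.39 correlation. Only the
CL–V1 covariance is nonzero. Residual error is proportional with SD 0.19.

## Simulation engine

The ODE system is integrated piecewise between infusion on/off boundaries
with adaptive RK45 at relative tolerance 1e-8 (solver default; the
constant-clearance analytic bi-exponential solution is kept in the test
suite as an independent oracle, and the numeric solution matches it to
~1e-9 relative error). A population sharing one dose/observation schedule
is integrated as a single stacked 2n-state system; this batching is what
makes population fits, bootstrap and VPC affordable on one CPU.

Infusion duration is not documented for the source analysis; the default
is 1 h (standard mAb administration). Only Cmax is sensitive to this
choice. Simulated observations below a configured LLOQ are flagged, not
censored.

## Exposure metrics and regimen comparison

Interval metrics use trapezoidal AUC on a dense grid (≥200 points
solved; <50 points is rejected), Cavg = AUC/τ exactly, Ctrough at the
interval end. First-dose metrics integrate the full time-varying model
over the regimen's own interval (504 h for Q3W, 336 h for Q2W — the two
regimens are compared each over its own τ). Steady state follows the
post-hoc convention: clearance is frozen at CL_ss = CL_base·exp(Emax_i)
and doses are superposed until successive troughs agree to 1e-4 (the
needed dose count is predicted from the terminal rate constant, capped at
200). The identity AUC_ss = dose/CL_ss is asserted to 0.5% on every call.
A cross-check integrates the full time-varying system to 15×T50 and
requires trough agreement within 2%; at γ = 1.32 the sigmoid is only ~89%
complete at 5×T50 (trough gap ~7%), so a longer horizon is the correct
validation point for the frozen-CL shortcut.

Regimen comparison uses per-subject paired log differences: GMR =
exp(mean d) with a 90% CI from the normal 1.645 quantile on the paired SE
(the source does not specify t vs normal; at the simulated n the
difference is negligible). Coverage is the percent of flat-dose subjects
inside the 2.5–97.5 percentile band of the weight-based arm.

## Estimation

Full FOCE-I is not re-implemented. The marginal −2 log-likelihood (OFV)
uses the Laplace approximation around each subject's MAP random effects:
per trial of the fixed effects, subject modes are found by damped
Gauss-Newton (finite-difference Jacobians, batched across subjects, warm
started between outer iterations), and the Hessian in the Laplace term is
the Gauss-Newton approximation J'WJ + Ω⁻¹. The outer search is
Nelder-Mead on transformed parameters (log scale for positive ones),
relative tolerances ~1e-3. Because inner modes are iterated to a gradient
tolerance sitting above the finite-difference noise floor, the OFV is
reproducible to ~1e-3 and invariant to subject ordering. "Successful
minimization" means outer convergence with a finite OFV and positive
definite Laplace Hessians, mirroring the bootstrap success counting.

Consequences to keep in mind: parameter recovery on simulated data, not
estimate-for-estimate equality with the published NONMEM fit, is the
supported claim; recovery experiments at n = 200 with rich sampling
return the structural parameters within ~8% (the acceptance tolerance is
15%). Empirical-Bayes modes on noise-free data are biased by the
proportional-error interaction term (the ln f normalization) by order σ²;
exact recovery tests therefore pair noise-free data with a small residual
SD, as any likelihood-consistent implementation must.

BLQ observations are excluded from the likelihood by default (a switch
includes them); the source text only says likelihood-based imputation
"was considered", so neither disposition is asserted as fact.

The stepwise covariate search adds the candidate with the largest OFV
drop while ΔOFV ≥ χ²(1−0.01, df) (6.63 at 1 df) and then removes terms
whose ΔOFV on removal is below χ²(1−0.001, df) (10.83 at 1 df);
multi-level categorical candidates carry their own df. The bootstrap
resamples subjects with replacement and summarizes successful refits by
2.5/50/97.5 percentiles.

The pcVPC bins observations into equal-count bins of time after the
previous dose (default 10; bins under 5 observations merge with a
neighbor), corrects each DV by bin-median population prediction over the
subject's own population prediction, applies the same correction to every
simulated replicate, and reports 95% prediction intervals of the binned
p5/p50/p95 across replicates.

## Exposure-response

Cave for E-R is the model-derived first-dose interval average by default
(the source does not state which interval; a steady-state switch exists).
Logistic models are ML fits (statsmodels GLM/binomial); curve CIs use the
delta method on the linear predictor. Backward elimination minimizes AIC
with the exposure term protected — note that AIC retains a pure-noise
term whenever its deviance exceeds 2 (probability ≈ 0.157), so "all noise
removed" is not an attainable guarantee; the expected removal fraction
(≈ 0.84 per term) is what the tests check. Survival analysis uses
lifelines: product-limit KM curves, the multi-group log-rank test, and
Cox PH with Efron tie handling (ties method not documented in the
source). Exposure quartiles are left-closed empirical quartiles of
treated-arm Cave only, Q1 lowest; the control arm is its own group.
Candidate covariates for the Cox model must be log-rank significant
(p < 0.001) in both arms separately.

## Synthetic data

The covariate generator states the published world where it can: weight
is log-normal with (µ, σ) least-squares-fitted to the printed median 63.5
and 5th/95th percentiles 46.6/89.4 kg (a single log-normal cannot match
all three exactly; the compromise is within ~2% of each), truncated by
re-draw to the observed 31.6–164 kg range. Laboratory covariates are
log-normal around the model reference medians with invented but plausible
CVs (albumin 15%, LDH 40%, CRCL 30%); sex (70% male), race (90/6/4%
Asian/White/other) and ADA positivity (10%) reflect a predominantly
Chinese multi-tumor population. Covariates are drawn independently — the
true joint distribution is unpublished, which is exactly why printed
population-level exposure tables (geometric means, the 0.795–0.797
relative-exposure column, the 88–96% coverage figures) are not
reproduction targets; the package checks the distribution-free properties
of those statistics instead.

The trial generator defaults to the flat truth the analysis reports: zero
exposure slopes on safety and response endpoints (intercepts calibrated
to the published incidences 0.78/0.68/0.53 and a 0.50 response rate), and
exponential PFS with a constant treatment-vs-control hazard ratio of 0.3
(~70% risk reduction) independent of exposure quartile, with independent
exponential censoring (default 20%) and a control median of 35 weeks
(arm-level medians are not in the source text; this is a design choice on
the weekly time scale). The deterministic 152-row safety fixture encodes
exactly 118/103/81 positives with nested AE categories (an assumption
needed only for one coherent table) and a fixed modular-stride assignment
so the flags are uncorrelated with the exposure column.

A green test suite therefore establishes: the model equations and their
worked examples, solver correctness against closed forms, the statistical
calibration of every inferential procedure on data generated by the
package's own stated world — not agreement with the unpublished
patient-level data.

## Numerical choices and edge cases

- Predictions are floored at 1e-6 µg/mL inside the proportional-error
  likelihood so pre-dose zeros cannot produce infinite weights.
- Nelder-Mead was chosen for the outer problem because the Laplace OFV
  carries ~1e-3-level noise from the inner iterations, which defeats
  finite-difference quasi-Newton methods.
- Dosing events and observation schedules are matched to 1e-9 h when
  grouping subjects for batched solves; unmatched subjects fall back to
  singleton groups, so heterogeneous datasets are merely slower, not
  wrong.
- Desk-scale defaults (subjects, bootstrap replicates, VPC simulations)
  are reduced from the source analysis' 1,014 patients / 1,000 replicates
  / 500 simulations to keep the suite in minutes on one CPU; every such
  reduction is in the tests, not in the methods.

## Known limitations

- No subcutaneous absorption, target-mediated disposition, nonlinear
  elimination, or interoccasion variability; no covariates on Q or V2.
- Laplace-around-MAP differs from NONMEM FOCE-I in the Hessian detail;
  OFV values are not comparable across implementations, only within.
- M3-style BLQ likelihood handling is not implemented (flag/exclude only).
- The forest CI from %RSE draws ignores parameter correlations.
- Independent-covariate synthetic populations understate the covariance
  of real covariates (e.g. weight with CRCL), so population-level
  exposure percentiles are indicative only.
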