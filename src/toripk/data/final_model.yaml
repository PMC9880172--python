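# Final population-PK model constants (typical values, covariate
# coefficients, reference covariate values, IIV %CVs, residual error).
# Values may be overridden by passing an edited copy via --model.
name: final-poppk-time-varying-cl
version: 1
fixed_effects:
  emax_tv: -0.444     # log-scale asymptotic CL change; exp(-0.444) = 0.64
  t50: 1580.0         # h (~65 days)
  gamma: 1.32
  cl_tv: 14.9         # mL/h
  v1_tv: 3710.0       # mL
  q_tv: 36.5          # mL/h
  v2_tv: 796.0        # mL
  cl_ada: 0.191
  cl_ldh: 0.161
  cl_female: -0.19
  cl_albumin: -0.676
  cl_weight: 0.097
  cl_crcl: 0.226
  v1_white: -0.23
  v1_other: -0.327
  v1_weight: 0.488
  ref_weight: 64.0    # kg
  ref_albumin: 43.7   # g/L
  ref_ldh: 199.0      # U/L
  ref_crcl: 94.31     # mL/min
random_effects:
  cv_emax: 0.39
  cv_cl: 0.31
  cv_v1: 0.27
  corr_cl_v1: 0.39
  sigma_prop: 0.19
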