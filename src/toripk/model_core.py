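"""Final population-PK model: structural constants, time-varying clearance,
covariate sub-models and covariate forest-plot effects.

The drug is a humanized anti-PD-1 IgG4 whose serum PK follows a linear
two-compartment disposition model with zero-order IV infusion, except that
clearance changes slowly over treatment time.  The time course of CL is a
sigmoidal-Emax function of time after the first dose,

    CL(t) = CL_base * exp(Emax_i * t^gamma / (T50^gamma + t^gamma)),

so CL moves from CL_base at t=0 toward CL_base*exp(Emax_i) asymptotically.
Covariates act multiplicatively on CL (ADA status, LDH, sex, albumin, body
weight, creatinine clearance) and on V1 (race, body weight): continuous
covariates as power terms scaled to the population reference value,
categorical ones as (1 + theta) factors relative to the reference category.

Units follow the pharmacometric convention used throughout the package:
amounts in mg, volumes in mL, times in hours, clearances in mL/h,
concentrations in ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FixedEffects",
    "RandomEffectsSpec",
    "CovariateProfile",
    "IndividualParameters",
    "cl_time_factor",
    "covariate_multiplier_cl",
    "covariate_multiplier_v1",
    "individual_parameters",
    "steady_state_clearance",
    "forest_effects",
    "load_model",
    "default_fixed_effects",
    "default_random_effects",
    "REFERENCE_PRESETS",
]


# Reference covariate values used in the final-model equations, and the
# slightly different reference patient used for the published forest plot.
REFERENCE_PRESETS = {
    "model": {"weight": 64.0, "albumin": 43.7, "ldh": 199.0, "crcl": 94.31},
    "forest": {"weight": 63.5, "albumin": 43.6, "ldh": 198.0, "crcl": 94.3},
}


@dataclass(frozen=True)
class FixedEffects:
    """Population (typical-value) parameters of the final PK model."""

    emax_tv: float = -0.444      # log-scale asymptotic CL change
    t50: float = 1580.0          # h, time to half the CL change
    gamma: float = 1.32          # sigmoidicity
    cl_tv: float = 14.9          # mL/h
    v1_tv: float = 3710.0        # mL
    q_tv: float = 36.5           # mL/h
    v2_tv: float = 796.0         # mL
    # covariate coefficients on CL
    cl_ada: float = 0.191
    cl_ldh: float = 0.161
    cl_female: float = -0.19
    cl_albumin: float = -0.676
    cl_weight: float = 0.097
    cl_crcl: float = 0.226
    # covariate coefficients on V1
    v1_white: float = -0.23
    v1_other: float = -0.327
    v1_weight: float = 0.488
    # reference covariate values
    ref_weight: float = 64.0     # kg
    ref_albumin: float = 43.7    # g/L
    ref_ldh: float = 199.0       # U/L
    ref_crcl: float = 94.31      # mL/min

    def __post_init__(self) -> None:
        if self.t50 <= 0 or self.gamma <= 0:
            raise ValueError("t50 and gamma must be positive")
        if self.cl_tv <= 0 or self.v1_tv <= 0 or self.v2_tv <= 0:
            raise ValueError("cl_tv, v1_tv and v2_tv must be positive")
        if self.q_tv < 0:
            raise ValueError("q_tv must be nonnegative")
        for name in ("ref_weight", "ref_albumin", "ref_ldh", "ref_crcl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_reference(self, preset: str) -> "FixedEffects":
        """Return a copy using a named reference-patient preset."""
        ref = REFERENCE_PRESETS[preset]
        return replace(
            self,
            ref_weight=ref["weight"],
            ref_albumin=ref["albumin"],
            ref_ldh=ref["ldh"],
            ref_crcl=ref["crcl"],
        )


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Between-subject variability and residual error.

    ``omega`` is the 3x3 variance-covariance of (eta_Emax, eta_CL, eta_V1).
    eta_CL and eta_V1 act on the exp scale (log-normal parameters); eta_Emax
    is additive on Emax.  Only the CL-V1 covariance is nonzero in the final
    model.  ``sigma_prop`` is the proportional residual SD.
    """

    omega: np.ndarray
    sigma_prop: float

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (3, 3):
            raise ValueError("omega must be 3x3")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        eig = np.linalg.eigvalsh(om)
        if eig.min() < -1e-12:
            raise ValueError("omega must be positive semi-definite")
        if om[0, 1] != 0 or om[0, 2] != 0:
            raise ValueError("only the CL-V1 covariance may be nonzero")
        if self.sigma_prop <= 0:
            raise ValueError("sigma_prop must be positive")
        object.__setattr__(self, "omega", om)

    @classmethod
    def from_cv(
        cls,
        cv_emax: float = 0.39,
        cv_cl: float = 0.31,
        cv_v1: float = 0.27,
        corr_cl_v1: float = 0.39,
        sigma_prop: float = 0.19,
    ) -> "RandomEffectsSpec":
        """Build omega from %CV values via omega^2 = ln(1 + CV^2)."""
        w = np.log1p(np.array([cv_emax, cv_cl, cv_v1]) ** 2)
        om = np.diag(w)
        om[1, 2] = om[2, 1] = corr_cl_v1 * np.sqrt(w[1] * w[2])
        return cls(omega=om, sigma_prop=sigma_prop)


_RACES = ("asian", "white", "other")
_SEXES = ("male", "female")


@dataclass(frozen=True)
class CovariateProfile:
    """One patient's covariates.

    ``candidates`` holds extra covariates that were screened during model
    development but not retained (age, liver enzymes, tumor burden, ECOG,
    combination-treatment flag, organ-impairment grades ...); they are only
    consulted by the stepwise covariate search.
    """

    weight: float = 64.0          # kg
    albumin: float = 43.7         # g/L
    ldh: float = 199.0            # U/L
    crcl: float = 94.31           # mL/min
    sex: str = "male"
    race: str = "asian"
    ada_positive: bool = False
    candidates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("weight", "albumin", "ldh", "crcl"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}")
        if self.race not in _RACES:
            raise ValueError(f"race must be one of {_RACES}")


@dataclass(frozen=True)
class IndividualParameters:
    """Per-patient realized parameters after covariates and random effects.

    ``cl_base`` is the covariate- and eta-adjusted clearance at time zero;
    the realized clearance at time t is ``cl_base * cl_time_factor(t, ...)``.
    """

    cl_base: float   # mL/h
    v1: float        # mL
    q: float         # mL/h
    v2: float        # mL
    emax_i: float
    t50: float       # h
    gamma: float

    def __post_init__(self) -> None:
        if self.cl_base <= 0 or self.v1 <= 0 or self.v2 <= 0:
            raise ValueError("cl_base, v1 and v2 must be positive")
        if self.q < 0:
            raise ValueError("q must be nonnegative")
        if self.t50 <= 0 or self.gamma <= 0:
            raise ValueError("t50 and gamma must be positive")

    def cl_at(self, t):
        """Clearance (mL/h) at time t hours after the first dose."""
        return self.cl_base * cl_time_factor(t, self.emax_i, self.t50, self.gamma)


def cl_time_factor(t, emax_i: float, t50: float, gamma: float):
    """Multiplicative change in CL at time ``t`` (h) after the first dose.

    Sigmoidal-Emax in time: ``exp(emax_i * t^gamma / (t50^gamma + t^gamma))``.
    Equals 1 at t=0, exp(emax_i/2) at t=t50, and tends to exp(emax_i).
    Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if t50 <= 0 or gamma <= 0:
        raise ValueError("t50 and gamma must be positive")
    tg = np.power(t, gamma)
    out = np.exp(emax_i * tg / (t50**gamma + tg))
    return out if out.ndim else float(out)


def covariate_multiplier_cl(profile: CovariateProfile, theta: FixedEffects) -> float:
    """Multiplicative covariate effect on CL relative to the reference patient.

    Reference: male, Asian, ADA-negative, continuous covariates at the model
    reference values — multiplier 1 by construction.
    """
    m = (
        (profile.ldh / theta.ref_ldh) ** theta.cl_ldh
        * (profile.albumin / theta.ref_albumin) ** theta.cl_albumin
        * (profile.weight / theta.ref_weight) ** theta.cl_weight
        * (profile.crcl / theta.ref_crcl) ** theta.cl_crcl
    )
    if profile.ada_positive:
        m *= 1.0 + theta.cl_ada
    if profile.sex == "female":
        m *= 1.0 + theta.cl_female
    return float(m)


def covariate_multiplier_v1(profile: CovariateProfile, theta: FixedEffects) -> float:
    """Multiplicative covariate effect on V1 (race and body weight)."""
    m = (profile.weight / theta.ref_weight) ** theta.v1_weight
    if profile.race == "white":
        m *= 1.0 + theta.v1_white
    elif profile.race == "other":
        m *= 1.0 + theta.v1_other
    return float(m)


def individual_parameters(
    theta: FixedEffects,
    profile: CovariateProfile,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
) -> IndividualParameters:
    """Realize one patient's parameters from covariates and eta draws.

    ``eta`` is (eta_Emax, eta_CL, eta_V1).  CL and V1 etas are exp-scale;
    the Emax eta is additive.  Q and V2 carry no IIV in the final model.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be 3 finite values (eta_Emax, eta_CL, eta_V1)")
    return IndividualParameters(
        cl_base=theta.cl_tv * covariate_multiplier_cl(profile, theta) * np.exp(eta[1]),
        v1=theta.v1_tv * covariate_multiplier_v1(profile, theta) * np.exp(eta[2]),
        q=theta.q_tv,
        v2=theta.v2_tv,
        emax_i=theta.emax_tv + eta[0],
        t50=theta.t50,
        gamma=theta.gamma,
    )


def steady_state_clearance(ind: IndividualParameters) -> float:
    """Steady-state clearance CL_ss = cl_base * exp(emax_i), mL/h.

    This is the t->infinity limit of the time-varying clearance and is used
    for post-hoc steady-state exposure metrics.
    """
    return float(ind.cl_base * np.exp(ind.emax_i))


# ---------------------------------------------------------------------------
# covariate forest-plot machinery

_CLINICAL_RELEVANCE_BOUNDS = (0.80, 1.25)

# parameters of FixedEffects that are strictly positive and therefore drawn
# on the log scale when sampling parameter uncertainty
_LOG_SCALE = {"t50", "gamma", "cl_tv", "v1_tv", "q_tv", "v2_tv"}

# printed %RSE of the Table-1 estimates, used for uncertainty draws when no
# bootstrap replicate set is supplied
DEFAULT_RSE_PERCENT = {
    "emax_tv": 11, "t50": 17, "gamma": 14, "cl_tv": 2, "cl_ada": 24,
    "cl_ldh": 13, "cl_female": 11, "cl_albumin": 15, "cl_weight": 65,
    "cl_crcl": 17, "v1_tv": 3, "v1_white": 13, "v1_other": 10,
    "v1_weight": 18, "q_tv": 73, "v2_tv": 16,
}


def draw_fixed_effects(
    theta: FixedEffects,
    n_draws: int,
    rse_percent: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> list[FixedEffects]:
    """Sample parameter-uncertainty draws from independent normals on the
    estimation scale (log for positive structural parameters), using the
    printed %RSE values.  An approximation to the true estimation covariance;
    use bootstrap replicates where available.
    """
    rse = dict(DEFAULT_RSE_PERCENT)
    if rse_percent:
        rse.update(rse_percent)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        kw = {}
        for name, pct in rse.items():
            est = getattr(theta, name)
            se = abs(est) * pct / 100.0
            if name in _LOG_SCALE:
                kw[name] = est * np.exp(rng.normal(0.0, pct / 100.0))
            else:
                kw[name] = rng.normal(est, se)
        # keep invariants satisfiable under extreme draws
        kw["q_tv"] = max(kw["q_tv"], 0.0)
        draws.append(replace(theta, **kw))
    return draws


def forest_effects(
    theta_draws: Iterable[FixedEffects],
    scenarios: Sequence[tuple[str, Mapping[str, object]]],
    reference: CovariateProfile | None = None,
) -> pd.DataFrame:
    """Covariate effect-size table for a forest plot.

    Each scenario is ``(parameter, covariate_setting)`` with parameter in
    {"CL", "V1"} and ``covariate_setting`` a dict of CovariateProfile field
    overrides (e.g. ``{"weight": 46.6}``).  For every uncertainty draw the
    ratio of the parameter multiplier under the scenario to the reference
    patient is evaluated; the table reports the median and 2.5th/97.5th
    percentiles, and flags ratios whose point estimate falls outside the
    0.80-1.25 clinical-relevance band.
    """
    draws = list(theta_draws)
    if not draws:
        raise ValueError("theta_draws must contain at least one draw")
    reference = reference or CovariateProfile()
    mult = {"CL": covariate_multiplier_cl, "V1": covariate_multiplier_v1}
    rows = []
    for param, setting in scenarios:
        if param not in mult:
            raise ValueError("parameter must be 'CL' or 'V1'")
        profile = replace(reference, **setting)
        ratios = np.array(
            [mult[param](profile, th) / mult[param](reference, th) for th in draws]
        )
        med = float(np.median(ratios))
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        rows.append(
            {
                "parameter": param,
                "scenario": ", ".join(f"{k}={v}" for k, v in setting.items()),
                "ratio": med,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "clinically_relevant": not (
                    _CLINICAL_RELEVANCE_BOUNDS[0] <= med <= _CLINICAL_RELEVANCE_BOUNDS[1]
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model constants file

def load_model(path=None) -> tuple[FixedEffects, RandomEffectsSpec]:
    """Load (FixedEffects, RandomEffectsSpec) from a YAML model file.

    With no path, loads the packaged final-model constants.
    """
    if path is None:
        from importlib.resources import files

        text = files("toripk").joinpath("data/final_model.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    theta = FixedEffects(**doc["fixed_effects"])
    re_spec = RandomEffectsSpec.from_cv(**doc["random_effects"])
    return theta, re_spec


def default_fixed_effects() -> FixedEffects:
    return FixedEffects()


def default_random_effects() -> RandomEffectsSpec:
    return RandomEffectsSpec.from_cv()
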