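"""Exposure-response analysis: logistic safety/efficacy models with
AIC-based backward elimination (exposure term protected), Kaplan-Meier /
log-rank analysis of progression-free survival by exposure quartile, and
Cox proportional-hazards forest output.

Data conventions
----------------
An E-R table is a pandas DataFrame with one row per patient:

    cave          average concentration, ug/mL (positive for treated)
    ae_grade3, ae_trt_grade3, ae_discontinuation, orr
                  binary endpoints in {0, 1} (NaN allowed = missing)
    plus arbitrary covariate columns (ecog, liver_disease, arm, ...)

A survival table has columns ``time`` (weeks, > 0), ``event`` (1 =
progression/death, 0 = censored), ``arm`` ("treatment" or "control"),
``cave`` (treated only) and covariates.  Exposure quartiles are computed
from treated patients only, Q1 = lowest exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.special import expit

__all__ = [
    "IncidenceSummary",
    "LogisticER",
    "incidence_summary",
    "fit_logistic_er",
    "backward_eliminate_aic",
    "probability_curve",
    "assign_cave_quartiles",
    "km_logrank_by_quartile",
    "cox_forest",
    "select_km_predictors",
]

AE_ENDPOINTS = ("ae_grade3", "ae_trt_grade3", "ae_discontinuation")


class IncidenceSummary(NamedTuple):
    n_with: int
    n_without: int
    n_total: int
    rate: float  # rounded to 2 decimals


def incidence_summary(table: pd.DataFrame, endpoint: str) -> IncidenceSummary:
    """Counts and incidence rate (2 d.p.) for one binary endpoint."""
    if len(table) == 0:
        raise ValueError("empty E-R table")
    y = table[endpoint]
    if y.isna().any():
        raise ValueError(f"endpoint {endpoint!r} has missing values")
    n_with = int((y == 1).sum())
    n_total = int(len(y))
    return IncidenceSummary(
        n_with=n_with,
        n_without=n_total - n_with,
        n_total=n_total,
        rate=round(n_with / n_total, 2),
    )


@dataclass
class LogisticER:
    """A fitted logistic exposure-response model."""

    result: object            # statsmodels GLM results
    endpoint: str
    predictors: list[str]
    table: pd.DataFrame

    @property
    def aic(self) -> float:
        return float(self.result.aic)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def coefficient_table(self) -> pd.DataFrame:
        r = self.result
        ci = r.conf_int()
        return pd.DataFrame(
            {
                "coef": r.params,
                "se": r.bse,
                "p": r.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "odds_ratio": np.exp(r.params),
            }
        )


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    X = table[list(predictors)].astype(float) if predictors else pd.DataFrame(index=table.index)
    return sm.add_constant(X, has_constant="add")


def fit_logistic_er(
    table: pd.DataFrame,
    endpoint: str,
    predictors: Sequence[str] = ("cave",),
    min_events: int = 20,
) -> LogisticER:
    """Maximum-likelihood logistic fit of one endpoint on the predictors.

    Warns when either response class has fewer than ``min_events``
    members; raises on degenerate (single-class) or perfectly separated
    data, naming the offending predictors.
    """
    data = table.dropna(subset=[endpoint, *predictors])
    y = data[endpoint].astype(float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"endpoint {endpoint!r} is degenerate: {n1} events / {n0} non-events"
        )
    if min(n1, n0) < min_events:
        warnings.warn(
            f"only {min(n1, n0)} subjects in the smaller response class; "
            "fit may be unstable"
        )
    X = _design(data, predictors)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            result = model.fit()
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as err:
            raise ValueError(
                f"perfect separation fitting {endpoint!r} on {list(predictors)}"
            ) from err
    return LogisticER(result=result, endpoint=endpoint,
                      predictors=list(predictors), table=data)


def backward_eliminate_aic(
    model: LogisticER, protected: Sequence[str] = ("cave",)
) -> LogisticER:
    """Stepwise backward elimination by AIC with protected terms.

    Repeatedly removes the non-protected predictor whose removal lowers
    the AIC the most; stops when no removal lowers it.  Protected terms
    (the exposure metric by default) are never removed, regardless of
    significance.
    """
    current = model
    while True:
        removable = [p for p in current.predictors if p not in protected]
        if not removable:
            return current
        trials = []
        for p in removable:
            reduced = [q for q in current.predictors if q != p]
            try:
                trials.append(
                    fit_logistic_er(
                        current.table, current.endpoint, reduced, min_events=0
                    )
                )
            except ValueError:
                continue
        if not trials:
            return current
        best = min(trials, key=lambda m: m.aic)
        if best.aic < current.aic:
            current = best
        else:
            return current


def probability_curve(
    model: LogisticER,
    cave_grid: np.ndarray,
    at: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted event probability over an exposure grid with a delta-method
    CI on the linear predictor.

    Non-exposure predictors are held at ``at`` values (default: sample
    means).  Grid points outside the observed exposure range trigger a
    warning but are still evaluated.
    """
    cave_grid = np.asarray(cave_grid, dtype=float)
    obs = model.table["cave"]
    if cave_grid.min() < obs.min() or cave_grid.max() > obs.max():
        warnings.warn("exposure grid extends beyond the observed range")
    X = pd.DataFrame({"const": 1.0}, index=range(cave_grid.size))
    for p in model.predictors:
        if p == "cave":
            X[p] = cave_grid
        else:
            X[p] = (at or {}).get(p, float(model.table[p].mean()))
    X = X[model.result.params.index]
    lin = X.to_numpy() @ model.result.params.to_numpy()
    cov = model.result.cov_params().to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(), cov, X.to_numpy()))
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return pd.DataFrame(
        {
            "cave": cave_grid,
            "probability": expit(lin),
            "ci_low": expit(lin - z * se),
            "ci_high": expit(lin + z * se),
        }
    )


# ---------------------------------------------------------------------------
# survival


def assign_cave_quartiles(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``group`` column: control, or Q1..Q4 of treated-arm cave.

    Quartile breakpoints come from treated patients only (the control arm
    has no exposure); intervals are left-closed, Q1 = lowest exposure.
    """
    out = records.copy()
    treated = out["arm"] == "treatment"
    if treated.sum() == 0:
        raise ValueError("no treated patients")
    cave = out.loc[treated, "cave"]
    if cave.isna().any() or (cave <= 0).any():
        raise ValueError("treated patients must have positive cave")
    qs = np.quantile(cave.to_numpy(), [0.25, 0.5, 0.75])
    idx = np.searchsorted(qs, cave.to_numpy(), side="right")
    out["group"] = "control"
    out.loc[treated, "group"] = np.array(["Q1", "Q2", "Q3", "Q4"])[idx]
    out.attrs["quartile_bounds"] = [float(cave.min()), *map(float, qs), float(cave.max())]
    return out


def km_logrank_by_quartile(
    records: pd.DataFrame,
    at_risk_times: Sequence[float] | None = None,
) -> dict:
    """KM curves per exposure quartile (plus control) and the log-rank test.

    Returns a dict with the fitted ``lifelines`` KM estimators, the
    multi-group log-rank p-value and statistic, a number-at-risk table,
    and the quartile bounds.
    """
    df = assign_cave_quartiles(records)
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    groups = ["control", "Q1", "Q2", "Q3", "Q4"]
    curves: dict[str, KaplanMeierFitter] = {}
    for g in groups:
        sub = df[df["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g} has no subjects")
        kmf = KaplanMeierFitter(label=g)
        kmf.fit(sub["time"], sub["event"])
        curves[g] = kmf
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    if at_risk_times is None:
        at_risk_times = np.linspace(0, df["time"].max(), 7)[1:]
    n_at_risk = pd.DataFrame(
        {
            g: [
                int(((df["group"] == g) & (df["time"] >= t)).sum())
                for t in at_risk_times
            ]
            for g in groups
        },
        index=pd.Index(np.asarray(at_risk_times), name="time"),
    )
    return {
        "curves": curves,
        "logrank_p": float(lr.p_value),
        "logrank_stat": float(lr.test_statistic),
        "number_at_risk": n_at_risk,
        "quartile_bounds": df.attrs["quartile_bounds"],
        "data": df,
    }


def cox_forest(
    records: pd.DataFrame,
    covariates: Sequence[str] = (),
    min_events_per_coef: int = 10,
) -> pd.DataFrame:
    """Cox PH fit with exposure quartiles as predictors vs control.

    Ties are handled by Efron's method (the lifelines default).  Returns a
    forest table with hazard ratios, 95% CIs, p-values, and the implied
    risk reduction 1 - HR for each quartile.
    """
    df = assign_cave_quartiles(records)
    X = pd.get_dummies(df["group"], prefix="grp").drop(columns="grp_control")
    X = X.astype(float)
    for c in covariates:
        X[c] = df[c].astype(float)
    X["time"] = df["time"].astype(float)
    X["event"] = df["event"].astype(int)
    n_events = int(X["event"].sum())
    n_coef = X.shape[1] - 2
    if n_events < min_events_per_coef * n_coef:
        warnings.warn(
            f"{n_events} events for {n_coef} coefficients; "
            "hazard ratios may be unstable"
        )
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model did not converge: {err}") from err
    summ = cph.summary
    out = pd.DataFrame(
        {
            "term": summ.index,
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["risk_reduction"] = 1.0 - out["hr"]
    out.attrs["model"] = cph
    return out


def select_km_predictors(
    records: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.001,
) -> list[str]:
    """Candidate covariates log-rank-significant in both arms.

    Runs a per-candidate log-rank test within the control arm and within
    the treatment arm; a candidate is returned only when p < ``alpha`` in
    both, mirroring the screening rule used before the Cox fit.
    """
    selected = []
    for cand in candidates:
        ps = []
        for arm in ("control", "treatment"):
            sub = records[records["arm"] == arm]
            if sub[cand].nunique() < 2:
                ps.append(1.0)
                continue
            lr = multivariate_logrank_test(sub["time"], sub[cand], sub["event"])
            ps.append(float(lr.p_value))
        if max(ps) < alpha:
            selected.append(cand)
    return selected
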