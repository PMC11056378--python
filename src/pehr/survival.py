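"""Kaplan–Meier estimation, log-rank testing and Cox regression.

The endpoint throughout is 90-day all-cause mortality with administrative
censoring at the horizon. KM curves and log-rank statistics come from
lifelines; Cox models are fit by maximum partial likelihood through
statsmodels' ``PHReg`` (Efron tie handling by default, Breslow by flag),
with Wald confidence intervals and p-values on the log-hazard scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .errors import DataValidationError, ModelFitError

log = logging.getLogger(__name__)


@dataclass
class KMFit:
    """Product-limit estimate for one group.

    ``timeline`` holds the distinct observed times (events and censorings),
    with ``survival`` the right-continuous step-function values and
    ``variance`` the Greenwood variance estimate at each time.
    """

    label: object
    timeline: np.ndarray
    at_risk: np.ndarray
    observed: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.label,
            "time": self.timeline,
            "at_risk": self.at_risk,
            "events": self.observed,
            "survival": self.survival,
            "greenwood_variance": self.variance,
        })


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    tie_method: str
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coef": self.coef,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
        })

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {"coef": self.coef[i], "hr": self.hr[i],
                "ci_low": self.ci_low[i], "ci_high": self.ci_high[i],
                "p": self.p[i]}


def km_fit(times: Sequence[float], events: Sequence[bool],
           groups: Optional[Sequence] = None) -> dict[object, KMFit]:
    """Kaplan–Meier estimate per group (single group under label 'all').

    Ties at a time are processed together and subjects censored at t stay
    at risk for events at t (standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise DataValidationError("km_fit: no subjects")
    labels = np.asarray(groups) if groups is not None \
        else np.array(["all"] * len(times))
    out: dict[object, KMFit] = {}
    for lab in pd.unique(labels):
        mask = labels == lab
        if mask.sum() == 0:
            raise DataValidationError(f"km_fit: empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
            and kmf.event_table["observed"].iloc[0] == 0 \
            and kmf.event_table["censored"].iloc[0] == 0 else kmf.event_table
        timeline = tab.index.to_numpy(dtype=float)
        at_risk = tab["at_risk"].to_numpy(dtype=float)
        observed = tab["observed"].to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(timeline).to_numpy()
        # Greenwood: var(S(t)) = S(t)^2 * cumsum(d / (n (n - d)))
        with np.errstate(divide="ignore", invalid="ignore"):
            incr = np.where(at_risk > observed,
                            observed / (at_risk * (at_risk - observed)), 0.0)
        variance = surv ** 2 * np.cumsum(incr)
        out[lab] = KMFit(label=lab, timeline=timeline, at_risk=at_risk,
                         observed=observed, survival=surv,
                         variance=variance, n=int(mask.sum()))
    return out


def survival_at(fit: KMFit, t: float) -> float:
    """Right-continuous step-function value of the KM curve at time t."""
    if t < 0:
        raise DataValidationError("survival_at: t must be >= 0")
    if fit.timeline.size and t > fit.timeline[-1]:
        log.warning("survival_at: t=%g beyond last observed time %g; "
                    "returning last value", t, fit.timeline[-1])
    idx = np.searchsorted(fit.timeline, t, side="right") - 1
    return 1.0 if idx < 0 else float(fit.survival[idx])


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 groups: Sequence) -> tuple[float, float]:
    """Log-rank chi-square test across groups ((k-1) d.f.)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise DataValidationError("logrank_test: need at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(data: pd.DataFrame, covariates: Sequence[str],
            duration_col: str = "time", event_col: str = "event",
            tie_method: str = "efron") -> CoxFit:
    """Fit a Cox proportional-hazards model by maximum partial likelihood.

    ``covariates`` must be numeric (binary flags encoded 0/1) and
    non-constant. Wald 95 % CIs and p-values are computed on the
    log-hazard scale.
    """
    if tie_method not in ("efron", "breslow"):
        raise ModelFitError(f"unknown tie method {tie_method!r}")
    covariates = list(covariates)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise DataValidationError(f"cox_fit: covariates absent: {missing}")
    X = data[covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DataValidationError("cox_fit: missing values in covariates "
                                  "(impute first)")
    const = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
    if const:
        raise ModelFitError(f"cox_fit: constant covariate(s) {const}")
    times = data[duration_col].to_numpy(dtype=float)
    events = data[event_col].to_numpy(dtype=float)
    model = PHReg(times, X, status=events, ties=tie_method)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ModelFitError(f"cox_fit failed: {exc}") from exc
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(se))):
        raise ModelFitError(
            "cox_fit: non-finite estimates (possible separation or "
            "non-convergence); consider penalization or fewer covariates")
    if np.any(np.abs(coef) > 15):
        raise ModelFitError(
            "cox_fit: diverging coefficient (complete separation likely); "
            "penalization is required but out of scope")
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    return CoxFit(
        terms=covariates, coef=coef, se=se, hr=np.exp(coef),
        ci_low=np.exp(coef - zcrit * se), ci_high=np.exp(coef + zcrit * se),
        p=p, log_likelihood=float(model.loglike(res.params)),
        tie_method=tie_method, n=len(data), n_events=int(events.sum()))


def censor_at_horizon(data: pd.DataFrame, horizon_days: float = 90.0,
                      duration_col: str = "time",
                      event_col: str = "event") -> pd.DataFrame:
    """Administratively censor follow-up at the horizon before fitting."""
    out = data.copy()
    over = out[duration_col] > horizon_days
    out.loc[over, duration_col] = horizon_days
    out.loc[over, event_col] = 0
    out[event_col] = out[event_col].astype(int)
    return out
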