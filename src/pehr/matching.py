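"""Propensity-score estimation, caliper matching, IPW and balance checks.

The propensity score is the modelled probability of the tachycardia
exposure given baseline covariates (default set: age, ventilation, SOFA,
the variables most predictive of exposure). Exposed subjects are matched
1:1 to controls by nearest logit-propensity distance without replacement,
within a caliper of 0.2 standard deviations of the logit propensity score
(Austin's convention). Inverse-probability (ATE) weights share the same
model. Balance is judged by absolute standardized mean differences, with
0.1 the conventional threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataValidationError, ModelFitError


@dataclass
class MatchResult:
    """Outcome of 1:1 caliper matching."""

    pairs: pd.DataFrame            # exposed_id, control_id, distance
    caliper: float
    n_exposed: int
    n_control: int
    n_matched: int
    n_unmatched_exposed: int
    smd: Optional[pd.DataFrame] = None  # covariate, crude, matched

    @property
    def matched_ids(self) -> list:
        return list(self.pairs["exposed_id"]) + list(self.pairs["control_id"])


def estimate_propensity(data: pd.DataFrame, covariates: Sequence[str],
                        exposure_col: str = "exposed") -> pd.DataFrame:
    """Logistic propensity model fit by maximum likelihood.

    Returns a copy of ``data`` with ``ps`` and ``logit_ps`` columns; the
    score is clipped away from 0/1 only by floating-point necessity, never
    trimmed.
    """
    covariates = list(covariates)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise DataValidationError(f"estimate_propensity: absent: {missing}")
    y = data[exposure_col].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataValidationError("exposure must be binary 0/1")
    X = sm.add_constant(data[covariates].to_numpy(dtype=float))
    if np.isnan(X).any():
        raise DataValidationError("estimate_propensity: missing covariate "
                                  "values (impute first)")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ModelFitError(f"propensity model failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 30):
        raise ModelFitError("propensity model: separation suspected")
    ps = np.asarray(res.predict(X), dtype=float)
    eps = 1e-12
    ps = np.clip(ps, eps, 1 - eps)
    out = data.copy()
    out["ps"] = ps
    out["logit_ps"] = np.log(ps / (1 - ps))
    return out


def nn_match(ps_data: pd.DataFrame, caliper_multiplier: float = 0.2,
             seed: int = 0, exposure_col: str = "exposed",
             id_col: str = "subject_id",
             caliper: Optional[float] = None) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity score.

    The caliper is ``caliper_multiplier`` times the SD of the logit score
    over all subjects (an explicit ``caliper`` on the logit scale
    overrides it). Exposed subjects are processed in seeded-random order;
    each takes the nearest still-unmatched control within the caliper,
    without replacement. Deterministic given the seed.
    """
    exposed = ps_data[ps_data[exposure_col].astype(bool)]
    control = ps_data[~ps_data[exposure_col].astype(bool)]
    if exposed.empty or control.empty:
        raise DataValidationError("nn_match: both arms must be nonempty")
    if caliper is None:
        caliper = caliper_multiplier * float(ps_data["logit_ps"].std(ddof=1))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exposed))
    e_ids = exposed[id_col].to_numpy()
    e_logit = exposed["logit_ps"].to_numpy()
    c_ids = control[id_col].to_numpy()
    c_logit = control["logit_ps"].to_numpy()
    available = np.ones(len(control), dtype=bool)
    pairs = []
    for i in order:
        d = np.abs(c_logit - e_logit[i])
        d[~available] = np.inf
        j = int(np.argmin(d))
        if d[j] <= caliper:
            available[j] = False
            pairs.append({"exposed_id": e_ids[i], "control_id": c_ids[j],
                          "distance": float(d[j])})
    if not pairs:
        raise ModelFitError("nn_match: no admissible matches within caliper")
    pairs_df = pd.DataFrame(pairs).sort_values("exposed_id") \
        .reset_index(drop=True)
    return MatchResult(pairs=pairs_df, caliper=caliper,
                       n_exposed=len(exposed), n_control=len(control),
                       n_matched=len(pairs_df),
                       n_unmatched_exposed=len(exposed) - len(pairs_df))


def ipw_weights(ps_data: pd.DataFrame, stabilized: bool = True,
                exposure_col: str = "exposed") -> pd.Series:
    """ATE inverse-probability-of-treatment weights.

    1/PS for the exposed, 1/(1-PS) for controls; the stabilized variant
    multiplies by the marginal (non-)exposure probability so weights
    average about 1 in each arm.
    """
    ps = ps_data["ps"].to_numpy(dtype=float)
    if np.any(ps <= 0) or np.any(ps >= 1):
        raise DataValidationError(
            "ipw_weights: propensity scores at 0/1; trimming would be "
            "required and is out of scope")
    z = ps_data[exposure_col].to_numpy(dtype=float)
    w = np.where(z == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    if stabilized:
        prev = z.mean()
        w = np.where(z == 1, prev, 1.0 - prev) * w
    return pd.Series(w, index=ps_data.index, name="ipw")


def _smd_one(x1: np.ndarray, x0: np.ndarray,
             w1: Optional[np.ndarray] = None,
             w0: Optional[np.ndarray] = None) -> float:
    def _moments(x, w):
        if w is None:
            return float(np.mean(x)), float(np.var(x, ddof=1))
        m = float(np.average(x, weights=w))
        return m, float(np.average((x - m) ** 2, weights=w))
    m1, v1 = _moments(x1, w1)
    m0, v0 = _moments(x0, w0)
    pooled = (v1 + v0) / 2.0
    diff = abs(m1 - m0)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / np.sqrt(pooled)


def smd_table(data: pd.DataFrame, covariates: Sequence[str],
              exposure_col: str = "exposed",
              pairs: Optional[pd.DataFrame] = None,
              weights: Optional[pd.Series] = None,
              id_col: str = "subject_id") -> pd.DataFrame:
    """Absolute standardized mean differences per covariate.

    Computed on the crude sample by default, on the matched sample when
    ``pairs`` is given, or on the weighted sample when ``weights`` is
    given. For a binary covariate the pooled SD is
    sqrt((p1(1-p1) + p0(1-p0))/2).
    """
    if pairs is not None and weights is not None:
        raise DataValidationError("smd_table: give pairs or weights, not both")
    if pairs is not None:
        keep = set(pairs["exposed_id"]) | set(pairs["control_id"])
        data = data[data[id_col].isin(keep)]
    z = data[exposure_col].astype(bool).to_numpy()
    rows = []
    for cov in covariates:
        x = data[cov].to_numpy(dtype=float)
        binary = set(np.unique(x)) <= {0.0, 1.0}
        w1 = w0 = None
        if weights is not None:
            w = weights.loc[data.index].to_numpy(dtype=float)
            w1, w0 = w[z], w[~z]
        if binary:
            def _p(xs, ws):
                return float(np.average(xs, weights=ws)) if ws is not None \
                    else float(np.mean(xs))
            p1, p0 = _p(x[z], w1), _p(x[~z], w0)
            pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
            diff = abs(p1 - p0)
            smd = (0.0 if diff == 0 else float("inf")) if pooled == 0 \
                else diff / np.sqrt(pooled)
        else:
            smd = _smd_one(x[z], x[~z], w1, w0)
        rows.append({"covariate": cov, "smd": smd})
    return pd.DataFrame(rows)


def matched_km(match: MatchResult, data: pd.DataFrame,
               duration_col: str = "time", event_col: str = "event",
               exposure_col: str = "exposed", id_col: str = "subject_id"):
    """KM curves and log-rank test restricted to the matched subjects."""
    from .survival import km_fit, logrank_test
    if match.pairs.empty:
        raise DataValidationError("matched_km: empty match set")
    sub = data[data[id_col].isin(match.matched_ids)]
    fits = km_fit(sub[duration_col], sub[event_col].astype(bool),
                  sub[exposure_col].astype(int))
    stat, p = logrank_test(sub[duration_col], sub[event_col].astype(bool),
                           sub[exposure_col].astype(int))
    return fits, stat, p
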