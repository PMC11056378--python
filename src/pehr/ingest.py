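"""Reading, validating and aggregating raw vitals and patient tables.

Raw heart-rate measurements arrive as long-format rows
``(subject_id, offset_minutes, heart_rate)`` with offsets counted from each
patient's own ICU admission. They are aggregated to hourly medians over
half-open hour bins [k, k+1), with empty bins explicitly missing, and the
cohort is then filtered by the inclusion rules: length of stay strictly
exceeding 24 h and at most 20 % of hourly bins missing. Covariates with more
than 10 % missing values are dropped; the rest are completed by single
predictive-mean-matching imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

VITALS_COLUMNS = ("subject_id", "offset_minutes", "heart_rate")

#: columns never dropped by variable screening or touched by imputation
PROTECTED_COLUMNS = ("subject_id", "time", "event", "death_offset_hours",
                     "los_hours", "exposed")


@dataclass
class HourlySeries:
    """Per-patient hourly-median heart-rate vector.

    ``values[k]`` is the median of all samples with offset in
    [60k, 60(k+1)) minutes, or NaN when the hour holds no samples.
    ``span_hours`` runs from admission to the last observed hour (or the
    hour of death when the stream was truncated by death).
    """

    subject_id: object
    values: np.ndarray  # float array, NaN == missing
    span_hours: int

    @property
    def fraction_missing(self) -> float:
        return float(np.isnan(self.values).sum()) / self.span_hours


# --------------------------------------------------------------------- I/O

def read_vitals(path: str | Path) -> pd.DataFrame:
    """Load and validate a long-format vitals CSV.

    Raises :class:`DataValidationError` naming the first offending row for
    out-of-range heart rates, negative offsets or duplicate
    (subject, offset) pairs.
    """
    df = pd.read_csv(path)
    missing = set(VITALS_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(
            f"{path}: missing columns {sorted(missing)}")
    for col in ("offset_minutes", "heart_rate"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise DataValidationError(
                f"{path}: unparseable {col} at row {bad[0] + 2}")
        df[col] = vals
    bad = df.index[df["heart_rate"].isna() | (df["heart_rate"] <= 0)
                   | (df["heart_rate"] >= 300)]
    if len(bad):
        raise DataValidationError(
            f"{path}: heart_rate out of (0, 300) at row {bad[0] + 2}")
    bad = df.index[df["offset_minutes"].isna() | (df["offset_minutes"] < 0)]
    if len(bad):
        raise DataValidationError(
            f"{path}: negative or missing offset_minutes at row {bad[0] + 2}")
    dup = df.duplicated(["subject_id", "offset_minutes"])
    if dup.any():
        raise DataValidationError(
            f"{path}: duplicate (subject_id, offset_minutes) at row "
            f"{df.index[dup][0] + 2}")
    return df.sort_values(["subject_id", "offset_minutes"],
                          kind="mergesort").reset_index(drop=True)


def read_patients(path: str | Path) -> pd.DataFrame:
    """Load the per-patient covariate/outcome table."""
    df = pd.read_csv(path)
    required = {"subject_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate subject_id")
    times = pd.to_numeric(df["time"], errors="coerce")
    bad = df.index[times.isna() | (times <= 0)]
    if len(bad):
        raise DataValidationError(
            f"{path}: non-positive or unparseable time at row {bad[0] + 2}")
    df["time"] = times
    df["event"] = df["event"].astype(bool)
    return df


# ------------------------------------------------------------- aggregation

def hourly_medians(vitals: pd.DataFrame,
                   death_hours: Optional[Mapping[object, float]] = None
                   ) -> dict[object, HourlySeries]:
    """Aggregate per-subject samples to hourly medians.

    ``death_hours`` maps subjects whose stream was truncated by in-ICU
    death to the death offset in hours; their span is extended/truncated to
    the hour of death so terminal missingness is accounted against the
    stay, not silently dropped.
    """
    death_hours = death_hours or {}
    out: dict[object, HourlySeries] = {}
    vit = vitals.sort_values(["subject_id", "offset_minutes"], kind="mergesort")
    hours = (vit["offset_minutes"].to_numpy() // 60).astype(np.int64)
    for sid, idx in vit.groupby("subject_id", sort=False).indices.items():
        h = hours[idx]
        hr = vit["heart_rate"].to_numpy()[idx]
        span = int(h.max()) + 1
        if sid in death_hours and np.isfinite(death_hours[sid]):
            span = max(span, int(np.ceil(death_hours[sid])))
        values = np.full(span, np.nan)
        # within a subject, samples are offset-sorted, so each bin's slice
        # is contiguous
        boundaries = np.flatnonzero(np.diff(h)) + 1
        for chunk, hour in zip(np.split(hr, boundaries),
                               np.concatenate([[h[0]], h[boundaries]])
                               if boundaries.size else [h[0]]):
            if hour < span:
                values[hour] = float(np.median(chunk))
        out[sid] = HourlySeries(subject_id=sid, values=values,
                                span_hours=span)
    return out


# ---------------------------------------------------------------- filters

def apply_inclusion_filters(patients: pd.DataFrame,
                            series_map: Mapping[object, HourlySeries],
                            min_los_hours: float = 24.0,
                            max_missing_fraction: float = 0.20
                            ) -> tuple[list, pd.DataFrame]:
    """Apply the cohort inclusion rules; returns (retained ids, exclusion log).

    A subject is retained iff length of stay strictly exceeds
    ``min_los_hours`` AND at most ``max_missing_fraction`` of hourly bins
    are missing. Exactly one reason is logged per excluded subject, first
    failing rule in the order: no vitals, length of stay, missingness.
    """
    retained: list = []
    excluded: list[dict] = []
    for _, row in patients.iterrows():
        sid = row["subject_id"]
        if sid not in series_map:
            excluded.append({"subject_id": sid, "reason": "no vitals"})
            continue
        los = float(row["los_hours"]) if "los_hours" in patients.columns \
            else float(series_map[sid].span_hours)
        if not los > min_los_hours:
            excluded.append({"subject_id": sid,
                             "reason": f"los <= {min_los_hours:g} h"})
            continue
        frac = series_map[sid].fraction_missing
        if frac > max_missing_fraction:
            excluded.append({
                "subject_id": sid,
                "reason": f"missing fraction {frac:.3f} > "
                          f"{max_missing_fraction:g}"})
            continue
        retained.append(sid)
    log = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    return retained, log


def screen_variables(patients: pd.DataFrame, threshold: float = 0.10,
                     protected: Sequence[str] = PROTECTED_COLUMNS
                     ) -> list[str]:
    """Columns to keep: drop covariates with missing fraction strictly
    above ``threshold``. Outcome/exposure/identifier columns are never
    dropped."""
    keep = []
    n = len(patients)
    for col in patients.columns:
        if col in protected:
            keep.append(col)
            continue
        frac = float(patients[col].isna().sum()) / n if n else 0.0
        if frac <= threshold:
            keep.append(col)
    return keep


# ------------------------------------------------------------- imputation

def pmm_impute(patients: pd.DataFrame, k_donors: int = 5, seed: int = 0,
               variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Single predictive-mean-matching imputation (type-1 PMM).

    For each incomplete variable, a linear predictor on the other
    covariates is fit by least squares on complete cases; each missing cell
    is filled with the *observed* value of one of the ``k_donors`` donors
    whose predicted values lie nearest the recipient's prediction (ties at
    the k-th distance all enter the donor pool). Observed cells are never
    altered, and imputed values always lie in the variable's observed
    support.
    """
    rng = np.random.default_rng(seed)
    df = patients.copy()
    candidates = [c for c in df.columns if c not in PROTECTED_COLUMNS
                  and pd.api.types.is_numeric_dtype(df[c])]
    targets = variables if variables is not None else \
        [c for c in candidates if df[c].isna().any()]
    for col in targets:
        obs_mask = df[col].notna().to_numpy()
        mis_mask = ~obs_mask
        if not mis_mask.any():
            continue
        n_obs = int(obs_mask.sum())
        if n_obs < k_donors:
            raise DataValidationError(
                f"pmm_impute: variable {col!r} has only {n_obs} complete "
                f"cases; choose k_donors <= {n_obs}")
        predictors = [c for c in candidates if c != col]
        X = df[predictors].to_numpy(dtype=float)
        # temporary mean-fill of predictor gaps for the linear model only
        col_means = np.nanmean(X, axis=0) if X.size else np.empty(0)
        if X.size:
            X = np.where(np.isnan(X), col_means, X)
        X = np.column_stack([np.ones(len(df)), X])
        y = df[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X[obs_mask], y[obs_mask], rcond=None)
        pred = X @ beta
        donor_pred = pred[obs_mask]
        donor_vals = y[obs_mask]
        filled = y.copy()
        for i in np.flatnonzero(mis_mask):
            d = np.abs(donor_pred - pred[i])
            kth = np.partition(d, k_donors - 1)[k_donors - 1]
            pool = donor_vals[d <= kth + 1e-12]  # include exact ties
            filled[i] = rng.choice(pool)
        df[col] = filled
    return df


# --------------------------------------------------------------- lab means

def average_first24h(labs: pd.DataFrame, value_col: str = "value",
                     window_hours: float = 24.0) -> pd.Series:
    """Per-subject arithmetic mean of lab samples drawn within the first
    24 h of admission; subjects with no in-window sample get NaN."""
    in_window = labs[labs["offset_minutes"] < window_hours * 60.0]
    means = in_window.groupby("subject_id")[value_col].mean()
    all_subjects = labs["subject_id"].unique()
    return means.reindex(all_subjects)
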