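"""Sensitivity grid over heart-rate thresholds and episode durations.

For every (threshold, duration) combination the cohort's exposure is
re-derived — duration d maps to the rule "d of d+1 consecutive hours",
generalizing the standard 11-of-12 pattern — and a minimally adjusted Cox
model (exposure + age + ventilation + SOFA by default) is refit. Cells
where exposure is constant or the fit fails are emitted with a reason code
rather than dropped. A containment check guards the detector: raising the
threshold or the duration can only shrink the positive set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import EpisodeRule, classify_cohort
from .errors import ModelFitError
from .ingest import HourlySeries
from .survival import cox_fit

GRID_COLUMNS = ["threshold", "duration", "n_positive", "hr", "ci_low",
                "ci_high", "p", "status"]


def rule_for_duration(threshold: float, duration: int,
                      min_terminal_run: int = 3) -> EpisodeRule:
    """Episode rule for a grid cell: duration d of a (d+1)-hour window."""
    return EpisodeRule(threshold=threshold, window_hours=duration + 1,
                       required_hours=duration,
                       min_terminal_run=min_terminal_run)


def run_grid(series_map: Mapping[object, HourlySeries],
             patients: pd.DataFrame,
             thresholds: Sequence[float] = (90, 95, 100, 105, 110, 115, 120),
             durations: Sequence[int] = tuple(range(6, 17)),
             adjust_covariates: Sequence[str] = ("age", "ventilation", "sofa"),
             min_terminal_run: int = 3, mode: str = "extended",
             fit_cox: bool = True,
             ) -> tuple[pd.DataFrame, dict[tuple[float, int], frozenset]]:
    """Exposure + minimally adjusted Cox hazard ratio per grid cell.

    Returns the tidy cell table and, for the containment check, the set of
    exposure-positive subjects per cell. ``fit_cox=False`` re-derives the
    exposure sets only (cells carry status ``not_fitted``), for detection
    diagnostics where the per-cell model is not needed.
    """
    rows = []
    positives: dict[tuple[float, int], frozenset] = {}
    for thr in thresholds:
        for dur in durations:
            rule = rule_for_duration(thr, int(dur), min_terminal_run)
            calls = classify_cohort(series_map, patients, rule, mode=mode)
            pos = frozenset(calls.loc[calls["exposed"], "subject_id"])
            positives[(thr, int(dur))] = pos
            cell = {"threshold": thr, "duration": int(dur),
                    "n_positive": len(pos), "hr": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p": np.nan, "status": "ok"}
            if not fit_cox:
                cell["status"] = "not_fitted"
                rows.append(cell)
                continue
            merged = patients.drop(columns=["exposed"], errors="ignore") \
                .merge(calls[["subject_id", "exposed"]], on="subject_id")
            merged["exposed"] = merged["exposed"].astype(int)
            if merged["exposed"].nunique() < 2:
                cell["status"] = "constant_exposure"
            else:
                try:
                    fit = cox_fit(merged,
                                  ["exposed", *adjust_covariates])
                    term = fit["exposed"]
                    cell.update(hr=term["hr"], ci_low=term["ci_low"],
                                ci_high=term["ci_high"], p=term["p"])
                except ModelFitError as exc:
                    cell["status"] = f"fit_failed: {exc}"
            rows.append(cell)
    return pd.DataFrame(rows, columns=GRID_COLUMNS), positives


def check_monotonicity(positives: Mapping[tuple[float, int], frozenset]
                       ) -> pd.DataFrame:
    """Positive-set containment across adjacent cells.

    For thresholds t2 >= t1 at fixed duration, positives(t2) must be a
    subset of positives(t1); likewise for longer durations at a fixed
    threshold. Returns one row per violated adjacency (empty on success).
    """
    thresholds = sorted({t for t, _ in positives})
    durations = sorted({d for _, d in positives})
    violations = []
    for d in durations:
        for t1, t2 in zip(thresholds, thresholds[1:]):
            extra = positives[(t2, d)] - positives[(t1, d)]
            if extra:
                violations.append({
                    "axis": "threshold", "from": t1, "to": t2, "fixed": d,
                    "n_escaping": len(extra)})
    for t in thresholds:
        for d1, d2 in zip(durations, durations[1:]):
            extra = positives[(t, d2)] - positives[(t, d1)]
            if extra:
                violations.append({
                    "axis": "duration", "from": d1, "to": d2, "fixed": t,
                    "n_escaping": len(extra)})
    return pd.DataFrame(violations,
                        columns=["axis", "from", "to", "fixed", "n_escaping"])
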