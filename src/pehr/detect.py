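"""Detection of prolonged elevated heart rate (peHR) episodes.

A patient's hourly-median heart-rate series is classified under two
definitions:

* **standard** — some window of ``window_hours`` consecutive hour bins
  contains at least ``required_hours`` bins whose median *strictly* exceeds
  the threshold (default: 11 of 12 consecutive hours above 100 bpm).
  Missing bins count as non-exceedance: an episode is never declared from
  unobserved hours.
* **extended** — the patient died while persistently tachycardic: no full
  window ever completed, but the last ``min_terminal_run`` or more observed
  hour bins immediately preceding death all strictly exceed the threshold.
  This rescues episodes censored by death. Standard status takes precedence
  when both could apply.

The module also ships :func:`brute_force_oracle`, a deliberately naive
window-enumeration reference used by the test suite to validate the
vectorized detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataValidationError
from .ingest import HourlySeries

NEGATIVE = "negative"
STANDARD = "standard"
EXTENDED = "extended"


@dataclass(frozen=True)
class EpisodeRule:
    """Parameters of the episode definition.

    ``required_hours`` of ``window_hours`` consecutive hourly medians must
    strictly exceed ``threshold`` bpm. ``min_terminal_run`` is the minimum
    length of the elevated run preceding death under the extended
    definition.
    """

    threshold: float = 100.0
    window_hours: int = 12
    required_hours: int = 11
    min_terminal_run: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.required_hours <= self.window_hours):
            raise ConfigError(
                "required_hours: need 1 <= required_hours <= window_hours")
        if self.threshold <= 0:
            raise ConfigError("threshold: must be > 0")
        if self.min_terminal_run < 1:
            raise ConfigError("min_terminal_run: must be >= 1")


@dataclass
class EpisodeCall:
    """Per-patient classification result."""

    subject_id: object
    status: str = NEGATIVE
    onset_hour: Optional[int] = None
    qualifying_window_count: int = 0
    notes: str = ""


def _exceedance(values: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean per-bin strict exceedance; NaN (missing) counts as False."""
    with np.errstate(invalid="ignore"):
        return np.greater(values, threshold, where=~np.isnan(values),
                          out=np.zeros(values.shape, dtype=bool))


def detect_standard(series: HourlySeries, rule: EpisodeRule) -> EpisodeCall:
    """Classify one series under the standard definition.

    A series shorter than the window is negative (flagged in ``notes``),
    not an error — such patients simply cannot complete a window.
    """
    values = np.asarray(series.values, dtype=float)
    if values.size == 0:
        raise DataValidationError(
            f"subject {series.subject_id}: empty hourly series")
    if values.size < rule.window_hours:
        return EpisodeCall(series.subject_id, NEGATIVE,
                           notes="window_exceeds_span")
    exceed = _exceedance(values, rule.threshold)
    counts = np.convolve(exceed.astype(np.int64),
                         np.ones(rule.window_hours, dtype=np.int64),
                         mode="valid")
    qualifying = counts >= rule.required_hours
    n_qual = int(qualifying.sum())
    if n_qual == 0:
        return EpisodeCall(series.subject_id, NEGATIVE)
    onset = int(np.argmax(qualifying))
    return EpisodeCall(series.subject_id, STANDARD, onset_hour=onset,
                       qualifying_window_count=n_qual)


def _terminal_run_length(values: np.ndarray, threshold: float) -> int:
    """Length of the trailing run of consecutive elevated *observed* bins.

    Trailing missing bins are skipped (death early within an hour can leave
    that bin empty); an interior missing bin terminates the run.
    """
    i = values.size - 1
    while i >= 0 and np.isnan(values[i]):
        i -= 1
    run = 0
    while i >= 0 and not np.isnan(values[i]) and values[i] > threshold:
        run += 1
        i -= 1
    return run


def detect_extended(series: HourlySeries, rule: EpisodeRule,
                    death_hour: Optional[float] = None) -> EpisodeCall:
    """Classify one series under the extended definition.

    Applies only to patients who died during observation (``death_hour``
    given). Standard positives are returned unchanged; a standard-negative
    decedent whose final observed bins form an elevated run of at least
    ``min_terminal_run`` hours is upgraded to ``extended``.
    """
    call = detect_standard(series, rule)
    if call.status == STANDARD or death_hour is None:
        return call
    if death_hour > series.span_hours + 1e-9:
        raise DataValidationError(
            f"subject {series.subject_id}: death_hour {death_hour} beyond "
            f"series span {series.span_hours}")
    values = np.asarray(series.values, dtype=float)
    run = _terminal_run_length(values, rule.threshold)
    if run >= rule.min_terminal_run:
        call.status = EXTENDED
        call.notes = (call.notes + ";" if call.notes else "") + \
            f"terminal_run={run}"
    return call


def classify_cohort(series_map: Mapping[object, HourlySeries],
                    patients: pd.DataFrame,
                    rule: EpisodeRule = EpisodeRule(),
                    mode: str = "extended") -> pd.DataFrame:
    """Classify every patient; returns one row per subject.

    ``mode='standard_only'`` is the sensitivity analysis: patients meeting
    only the extended criterion are classified negative. In either mode the
    returned frame has columns ``subject_id, status, onset_hour,
    qualifying_window_count, exposed, notes``.
    """
    if mode not in ("extended", "standard_only"):
        raise ConfigError(f"mode: unknown mode {mode!r}")
    rows = []
    pat = patients.set_index("subject_id")
    for sid in pat.index:
        if sid not in series_map:
            raise DataValidationError(
                f"subject {sid} has no hourly series (run inclusion filters "
                "before classification)")
        series = series_map[sid]
        death_hour = None
        if mode == "extended":
            dh = pat.at[sid, "death_offset_hours"] \
                if "death_offset_hours" in pat.columns else np.nan
            event = bool(pat.at[sid, "event"]) if "event" in pat.columns \
                else False
            if event and pd.notna(dh):
                # a death partway through the final hour may leave that bin
                # unobserved; clip to the series span
                death_hour = min(float(dh), float(series.span_hours))
        call = detect_extended(series, rule, death_hour) \
            if death_hour is not None else detect_standard(series, rule)
        rows.append({
            "subject_id": sid,
            "status": call.status,
            "onset_hour": call.onset_hour,
            "qualifying_window_count": call.qualifying_window_count,
            "exposed": call.status in (STANDARD, EXTENDED),
            "notes": call.notes,
        })
    return pd.DataFrame(rows)


def summarize_calls(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of standard / extended / negative classifications."""
    vc = calls["status"].value_counts()
    return {
        "n_standard": int(vc.get(STANDARD, 0)),
        "n_extended": int(vc.get(EXTENDED, 0)),
        "n_negative": int(vc.get(NEGATIVE, 0)),
    }


def brute_force_oracle(values: Iterable[float], rule: EpisodeRule,
                       return_onset: bool = False):
    """Reference standard-definition detector by explicit enumeration.

    Walks every possible window with plain Python loops. Intentionally
    naive; exists so the vectorized detector can be validated against an
    independent implementation.
    """
    vals = list(values)
    best_onset = None
    count = 0
    for start in range(0, len(vals) - rule.window_hours + 1):
        hits = 0
        for k in range(start, start + rule.window_hours):
            v = vals[k]
            if v is not None and not (isinstance(v, float) and np.isnan(v)) \
                    and v > rule.threshold:
                hits += 1
        if hits >= rule.required_hours:
            count += 1
            if best_onset is None:
                best_onset = start
    positive = count > 0
    if return_onset:
        return positive, best_onset, count
    return positive
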