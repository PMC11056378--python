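"""Shared fixtures: hand-built hourly series and constructed cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pehr.ingest import HourlySeries


def make_series(values, subject_id="s1") -> HourlySeries:
    """HourlySeries from a plain list; None/NaN mark missing bins."""
    vals = np.array([np.nan if v is None else float(v) for v in values])
    return HourlySeries(subject_id=subject_id, values=vals,
                        span_hours=len(vals))


def build_fixture_cohort(n_standard: int, n_extended: int, n_negative: int):
    """Zero-noise cohort with exact per-definition episode counts.

    Standard subjects carry a 14-h plateau at 110 bpm inside a 48-h stay;
    extended subjects die at hour 30 after a 5-h terminal run at 110 bpm
    (too short for any 11-of-12 window); negatives sit at 85 bpm
    throughout. Returns (series_map, patients table).
    """
    series_map = {}
    rows = []
    sid = 0
    for _ in range(n_standard):
        sid += 1
        vals = np.full(48, 85.0)
        vals[10:24] = 110.0
        series_map[sid] = HourlySeries(sid, vals, 48)
        rows.append({"subject_id": sid, "time": 90.0, "event": 0,
                     "death_offset_hours": np.nan, "los_hours": 48.0})
    for _ in range(n_extended):
        sid += 1
        vals = np.full(30, 85.0)
        vals[25:30] = 110.0
        series_map[sid] = HourlySeries(sid, vals, 30)
        rows.append({"subject_id": sid, "time": 30.0 / 24.0, "event": 1,
                     "death_offset_hours": 30.0, "los_hours": 30.0})
    for _ in range(n_negative):
        sid += 1
        series_map[sid] = HourlySeries(sid, np.full(48, 85.0), 48)
        rows.append({"subject_id": sid, "time": 90.0, "event": 0,
                     "death_offset_hours": np.nan, "los_hours": 48.0})
    return series_map, pd.DataFrame(rows)
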