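"""Ingestion: I/O validation, hourly binning, filters, PMM imputation."""

import numpy as np
import pandas as pd
import pytest

from pehr import SimulationConfig, simulate_cohort
from pehr.errors import DataValidationError
from pehr.ingest import (HourlySeries, apply_inclusion_filters,
                         average_first24h, hourly_medians, pmm_impute,
                         read_patients, read_vitals, screen_variables)

from conftest import make_series


def _write_vitals(tmp_path, rows):
    p = tmp_path / "vitals.csv"
    pd.DataFrame(rows, columns=["subject_id", "offset_minutes",
                                "heart_rate"]).to_csv(p, index=False)
    return p


class TestReaders:
    def test_well_formed_file_loads(self, tmp_path):
        p = _write_vitals(tmp_path, [(1, 0, 80), (1, 30, 85), (2, 10, 90)])
        df = read_vitals(p)
        assert len(df) == 3

    def test_negative_heart_rate_names_row(self, tmp_path):
        p = _write_vitals(tmp_path, [(1, 0, 80), (1, 30, -5)])
        with pytest.raises(DataValidationError, match="row 3"):
            read_vitals(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"subject_id": [1], "offset_minutes": [0]}) \
            .to_csv(p, index=False)
        with pytest.raises(DataValidationError, match="heart_rate"):
            read_vitals(p)

    def test_duplicate_offsets_rejected(self, tmp_path):
        p = _write_vitals(tmp_path, [(1, 0, 80), (1, 0, 85)])
        with pytest.raises(DataValidationError, match="duplicate"):
            read_vitals(p)

    def test_simulated_cohort_roundtrip(self, tmp_path):
        vitals, patients, _ = simulate_cohort(
            SimulationConfig(n_patients=25, seed=8))
        vp = tmp_path / "v.csv"
        pp = tmp_path / "p.csv"
        vitals.to_csv(vp, index=False, float_format="%.10g")
        patients.to_csv(pp, index=False, float_format="%.10g")
        v2 = read_vitals(vp)
        p2 = read_patients(pp)
        assert len(v2) == len(vitals)
        assert len(p2) == len(patients)
        np.testing.assert_allclose(
            np.sort(v2["heart_rate"]), np.sort(vitals["heart_rate"]),
            rtol=1e-9)


class TestHourlyMedians:
    def _frame(self, entries):
        return pd.DataFrame(entries, columns=["subject_id", "offset_minutes",
                                              "heart_rate"])

    def test_odd_count_median(self):
        v = self._frame([(1, 5, 90), (1, 20, 100), (1, 40, 110)])
        out = hourly_medians(v)[1]
        assert out.values[0] == 100

    def test_even_count_uses_mean_of_central_pair(self):
        v = self._frame([(1, 5, 90), (1, 40, 110)])
        assert hourly_medians(v)[1].values[0] == 100

    def test_empty_hours_are_missing_and_counted(self):
        v = self._frame([(1, 5, 90), (1, 150, 100)])  # hours 0 and 2
        s = hourly_medians(v)[1]
        assert s.span_hours == 3
        assert np.isnan(s.values[1])
        assert s.fraction_missing == pytest.approx(1 / 3)

    def test_death_hour_extends_span(self):
        v = self._frame([(1, 5, 90)])
        s = hourly_medians(v, {1: 4.5})[1]
        assert s.span_hours == 5
        assert s.fraction_missing == pytest.approx(4 / 5)

    def test_matches_sort_based_oracle_on_random_streams(self):
        rng = np.random.default_rng(11)
        rows = []
        for sid in range(40):
            n = rng.integers(5, 80)
            offs = np.sort(rng.uniform(0, 25 * 60, n))
            offs = np.unique(offs)
            hrs = rng.uniform(60, 140, offs.size)
            rows += [(sid, o, h) for o, h in zip(offs, hrs)]
        v = self._frame(rows)
        series = hourly_medians(v)
        for sid, grp in v.groupby("subject_id"):
            for hour in range(series[sid].span_hours):
                sel = grp[(grp.offset_minutes >= 60 * hour)
                          & (grp.offset_minutes < 60 * (hour + 1))]
                expected = np.median(np.sort(sel.heart_rate.to_numpy())) \
                    if len(sel) else np.nan
                got = series[sid].values[hour]
                assert (np.isnan(expected) and np.isnan(got)) \
                    or got == pytest.approx(expected)

    def test_binning_is_order_invariant(self):
        rng = np.random.default_rng(3)
        v = self._frame([(1, o, h) for o, h in
                         zip(rng.uniform(0, 600, 50), rng.uniform(60, 140, 50))])
        a = hourly_medians(v)[1]
        b = hourly_medians(v.sample(frac=1.0, random_state=0))[1]
        np.testing.assert_array_equal(a.values, b.values)


class TestInclusionFilters:
    def _patients(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "los_hours",
                                           "time", "event"])

    def _series(self, sid, span, n_missing):
        vals = np.full(span, 80.0)
        vals[:n_missing] = np.nan
        return {sid: HourlySeries(sid, vals, span)}

    def test_missingness_boundary_is_strict(self):
        # 21/100 missing -> excluded; 20/100 -> retained
        patients = self._patients([(1, 100, 90, 0), (2, 100, 90, 0)])
        series = {**self._series(1, 100, 21), **self._series(2, 100, 20)}
        retained, log = apply_inclusion_filters(patients, series)
        assert retained == [2]
        assert log.iloc[0]["reason"].startswith("missing fraction")

    def test_los_boundary_is_strict(self):
        patients = self._patients([(1, 24.0, 90, 0), (2, 24.5, 90, 0)])
        series = {**self._series(1, 25, 0), **self._series(2, 25, 0)}
        retained, log = apply_inclusion_filters(patients, series)
        assert retained == [2]
        assert "los" in log.iloc[0]["reason"]

    def test_first_failing_rule_wins_and_no_vitals_reason(self):
        patients = self._patients([(1, 10.0, 90, 0), (2, 50, 90, 0)])
        series = self._series(1, 10, 9)  # fails LOS *and* missingness
        retained, log = apply_inclusion_filters(patients, series)
        assert retained == []
        reasons = dict(zip(log.subject_id, log.reason))
        assert "los" in reasons[1]
        assert reasons[2] == "no vitals"

    def test_accounting_partition(self):
        patients = self._patients([(i, 30 + i, 90, 0) for i in range(6)])
        series = {i: HourlySeries(i, np.full(30, 80.0), 30)
                  for i in range(5)}
        retained, log = apply_inclusion_filters(patients, series)
        assert len(retained) + len(log) == len(patients)
        assert set(retained).isdisjoint(set(log.subject_id))


class TestVariableScreening:
    def test_strict_ten_percent_boundary(self):
        n = 100
        df = pd.DataFrame({
            "subject_id": range(n), "time": 1.0, "event": 0,
            "keep10": [np.nan] * 10 + list(range(90)),
            "drop11": [np.nan] * 11 + list(range(89)),
        })
        kept = screen_variables(df, 0.10)
        assert "keep10" in kept and "drop11" not in kept

    def test_outcome_columns_never_dropped(self):
        df = pd.DataFrame({"subject_id": [1, 2], "time": [np.nan, np.nan],
                           "event": [0, 1], "x": [1.0, 2.0]})
        kept = screen_variables(df, 0.10)
        assert {"time", "event", "subject_id"} <= set(kept)

    def test_complete_table_fully_retained(self):
        df = pd.DataFrame({"subject_id": [1], "time": [1.0], "event": [0],
                           "a": [1.0], "b": [2.0]})
        assert set(screen_variables(df)) == set(df.columns)


class TestPMMImputation:
    def _table(self, n=400, miss=0.08, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"subject_id": range(n), "time": 1.0, "event": 0,
                           "x": x, "y": y})
        holes = rng.random(n) < miss
        df.loc[holes, "y"] = np.nan
        return df, holes

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"subject_id": [1, 2, 3], "time": 1.0, "event": 0,
                           "a": [1.0, 2.0, 3.0]})
        out = pmm_impute(df, k_donors=2, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_imputed_values_lie_in_observed_support(self):
        df, holes = self._table()
        out = pmm_impute(df, k_donors=5, seed=1)
        observed = set(df.loc[~holes, "y"])
        assert set(out.loc[holes, "y"]) <= observed
        # observed cells untouched
        pd.testing.assert_series_equal(out.loc[~holes, "y"],
                                       df.loc[~holes, "y"])

    def test_mcar_mean_recovery(self):
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.normal(0, 1, n)
        y_full = 2.0 + 3.0 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"subject_id": range(n), "time": 1.0, "event": 0,
                           "x": x, "y": y_full.copy()})
        holes = rng.random(n) < 0.08
        df.loc[holes, "y"] = np.nan
        out = pmm_impute(df, k_donors=5, seed=3)
        se = y_full.std() / np.sqrt(n)
        assert abs(out["y"].mean() - y_full.mean()) < 3 * se

    def test_too_few_donors_raises(self):
        df = pd.DataFrame({"subject_id": range(4), "time": 1.0, "event": 0,
                           "a": [1.0, 2.0, np.nan, np.nan]})
        with pytest.raises(DataValidationError, match="k_donors"):
            pmm_impute(df, k_donors=5, seed=0)


class TestFirst24hAverages:
    def _labs(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "offset_minutes",
                                           "value"])

    def test_mean_of_in_window_samples(self):
        labs = self._labs([(1, 60, 10.0), (1, 600, 20.0)])
        assert average_first24h(labs)[1] == 15.0

    def test_out_of_window_only_is_missing(self):
        labs = self._labs([(1, 30 * 60, 10.0)])
        assert np.isnan(average_first24h(labs)[1])

    def test_matches_filter_then_mean_oracle(self):
        rng = np.random.default_rng(4)
        rows = [(sid, o, v) for sid in range(20)
                for o, v in zip(rng.uniform(0, 48 * 60, 15),
                                rng.normal(10, 2, 15))]
        labs = self._labs(rows)
        got = average_first24h(labs)
        for sid, grp in labs.groupby("subject_id"):
            sel = grp[grp.offset_minutes < 24 * 60]["value"]
            expected = sel.mean() if len(sel) else np.nan
            assert (np.isnan(expected) and np.isnan(got[sid])) \
                or got[sid] == pytest.approx(expected)
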