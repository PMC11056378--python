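"""Episode-detector behaviour: definitions, boundaries, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pehr.detect import (EXTENDED, NEGATIVE, STANDARD, EpisodeRule,
                         brute_force_oracle, classify_cohort, detect_extended,
                         detect_standard, summarize_calls)
from pehr.errors import ConfigError, DataValidationError

from conftest import build_fixture_cohort, make_series

RULE = EpisodeRule()


class TestStandardDefinition:
    def test_eleven_of_twelve_elevated_is_positive(self):
        # eleven bins at 105 and one dip to 95 inside one 12-h window
        vals = [105] * 6 + [95] + [105] * 5
        call = detect_standard(make_series(vals), RULE)
        assert call.status == STANDARD
        assert call.onset_hour == 0
        assert call.qualifying_window_count == 1

    def test_exactly_at_threshold_is_negative(self):
        # "exceeding 100" is strict: a flat series at 100 never qualifies
        call = detect_standard(make_series([100.0] * 24), RULE)
        assert call.status == NEGATIVE

    def test_ten_elevated_hours_insufficient(self):
        vals = [105] * 10 + [95, 95]
        assert detect_standard(make_series(vals), RULE).status == NEGATIVE

    def test_short_series_negative_not_error(self):
        call = detect_standard(make_series([110] * 5), RULE)
        assert call.status == NEGATIVE
        assert call.notes == "window_exceeds_span"

    def test_missing_bins_count_as_non_exceedance(self):
        # 11 elevated + 1 missing qualifies (11 of 12), but 10 + 2 missing
        # does not: unobserved hours never support an episode
        ok = [105] * 11 + [None]
        assert detect_standard(make_series(ok), RULE).status == STANDARD
        not_ok = [105] * 10 + [None, None]
        assert detect_standard(make_series(not_ok), RULE).status == NEGATIVE

    def test_onset_is_earliest_qualifying_window(self):
        # the window starting at hour 19 already holds 11 of 12 elevated
        # bins (one leading low hour is tolerated), so onset is 19
        vals = [90] * 20 + [105] * 12 + [90] * 5 + [105] * 12
        call = detect_standard(make_series(vals), RULE)
        assert call.onset_hour == 19

    def test_empty_series_rejected(self):
        with pytest.raises(DataValidationError):
            detect_standard(make_series([]), RULE)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ConfigError):
            EpisodeRule(window_hours=10, required_hours=11)


class TestExtendedDefinition:
    def test_death_truncated_run_is_extended(self):
        # death at hour 8 with hours 0-7 elevated: a full window was
        # impossible, the terminal run rescues the episode
        series = make_series([110] * 8)
        call = detect_extended(series, RULE, death_hour=8.0)
        assert call.status == EXTENDED

    def test_survivor_with_same_series_is_negative(self):
        series = make_series([110] * 8)
        assert detect_extended(series, RULE, death_hour=None).status \
            == NEGATIVE

    def test_standard_takes_precedence_over_extended(self):
        vals = [105] * 12 + [90] * 22 + [110] * 6
        call = detect_extended(make_series(vals), RULE, death_hour=40.0)
        assert call.status == STANDARD

    def test_terminal_run_below_minimum_stays_negative(self):
        vals = [85] * 10 + [110] * 2
        call = detect_extended(make_series(vals), RULE, death_hour=12.0)
        assert call.status == NEGATIVE

    def test_interior_gap_breaks_terminal_run(self):
        vals = [85] * 7 + [110, 110, None, 110, 110]
        call = detect_extended(make_series(vals), RULE, death_hour=12.0)
        assert call.status == NEGATIVE

    def test_trailing_missing_bin_skipped(self):
        # death early in an hour leaves that bin empty; the run before it
        # still counts
        vals = [85] * 7 + [110, 110, 110, 110, None]
        call = detect_extended(make_series(vals), RULE, death_hour=11.2)
        assert call.status == EXTENDED

    def test_death_beyond_span_rejected(self):
        with pytest.raises(DataValidationError):
            detect_extended(make_series([85] * 10), RULE, death_hour=50.0)


class TestCohortClassification:
    def test_constructed_counts_recovered_exactly(self):
        series_map, patients = build_fixture_cohort(312, 52, 381)
        calls = classify_cohort(series_map, patients, RULE, mode="extended")
        counts = summarize_calls(calls)
        assert counts["n_standard"] == 312
        assert counts["n_extended"] == 52
        std_only = classify_cohort(series_map, patients, RULE,
                                   mode="standard_only")
        assert summarize_calls(std_only)["n_standard"] == 312
        assert summarize_calls(std_only)["n_extended"] == 0

    def test_standard_only_positives_subset_of_extended_mode(self):
        series_map, patients = build_fixture_cohort(5, 4, 6)
        ext = classify_cohort(series_map, patients, RULE, mode="extended")
        std = classify_cohort(series_map, patients, RULE,
                              mode="standard_only")
        pos_ext = set(ext.loc[ext.exposed, "subject_id"])
        pos_std = set(std.loc[std.exposed, "subject_id"])
        assert pos_std <= pos_ext
        diff = ext[ext.subject_id.isin(pos_ext - pos_std)]
        assert (diff.status == EXTENDED).all()

    def test_missing_series_is_an_error(self):
        series_map, patients = build_fixture_cohort(1, 0, 1)
        del series_map[2]
        with pytest.raises(DataValidationError):
            classify_cohort(series_map, patients, RULE)

    def test_unknown_mode_rejected(self):
        series_map, patients = build_fixture_cohort(1, 0, 0)
        with pytest.raises(ConfigError):
            classify_cohort(series_map, patients, RULE, mode="bogus")


@st.composite
def random_series_and_rule(draw):
    n = draw(st.integers(min_value=1, max_value=72))
    vals = draw(st.lists(
        st.one_of(st.none(), st.floats(min_value=60, max_value=140)),
        min_size=n, max_size=n))
    thr = draw(st.sampled_from([90, 95, 100, 105, 110, 115, 120]))
    dur = draw(st.integers(min_value=6, max_value=16))
    return vals, EpisodeRule(threshold=thr, window_hours=dur + 1,
                             required_hours=dur)


class TestDetectorProperties:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(random_series_and_rule())
    def test_oracle_equivalence(self, case):
        """Vectorized detector must agree with window enumeration exactly."""
        vals, rule = case
        series = make_series(vals)
        call = detect_standard(series, rule)
        positive, onset, count = brute_force_oracle(vals, rule,
                                                    return_onset=True)
        assert (call.status == STANDARD) == positive
        if positive:
            assert call.onset_hour == onset
            assert call.qualifying_window_count == count

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(random_series_and_rule(),
           st.sampled_from([0.0, 2.5, 5.0, 10.0]))
    def test_threshold_monotonicity(self, case, bump):
        """Raising the threshold never converts a negative to a positive."""
        vals, rule = case
        lo = detect_standard(make_series(vals), rule).status == STANDARD
        stricter = EpisodeRule(rule.threshold + bump, rule.window_hours,
                               rule.required_hours)
        hi = detect_standard(make_series(vals), stricter).status == STANDARD
        assert not (hi and not lo)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(random_series_and_rule())
    def test_duration_monotonicity(self, case):
        """Raising required hours (d of d+1 pattern) never adds positives."""
        vals, rule = case
        d = rule.required_hours
        short = detect_standard(make_series(vals), rule).status == STANDARD
        longer = EpisodeRule(rule.threshold, d + 2, d + 1)
        long_pos = detect_standard(make_series(vals), longer).status \
            == STANDARD
        assert not (long_pos and not short)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(random_series_and_rule(), st.integers(0, 71))
    def test_adding_missing_bins_never_creates_positive(self, case, pos):
        vals, rule = case
        before = detect_standard(make_series(vals), rule).status == STANDARD
        degraded = list(vals)
        degraded[pos % len(degraded)] = None
        after = detect_standard(make_series(degraded), rule).status \
            == STANDARD
        assert not (after and not before)

    def test_detection_depends_on_hour_order(self):
        # 11 elevated hours spread thinly never qualify; packed together
        # they do — the statistic is order-sensitive by construction
        spread = ([105, 95, 95] * 11)[:33]
        packed = sorted(spread, reverse=True)
        assert detect_standard(make_series(spread), RULE).status == NEGATIVE
        assert detect_standard(make_series(packed), RULE).status == STANDARD
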