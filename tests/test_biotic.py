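"""CPUE standardization, weekly anomalies and monthly summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fjordlink.biotic import (
    NOMINAL_EFFORT,
    WeeklyCPUE,
    build_group_climatology,
    compute_weekly_cpue,
    detect_biotic_anomalies,
    monthly_summary,
    total_excluding,
    week_of_cohort,
)
from fjordlink.series_io import BIOTIC_GROUPS, TOTAL, SurveyRecord
from tests.conftest import flat_climatology


def record(week_start, effort=NOMINAL_EFFORT, **counts):
    base = {g: 0 for g in BIOTIC_GROUPS}
    base.update(counts)
    return SurveyRecord(
        week_start=pd.Timestamp(week_start), image_pairs=effort, counts=base
    )


def weekly_rows(values, group=TOTAL, start="2014-08-01"):
    """Weekly CPUE rows on consecutive cohort weeks with given values."""
    anchor = pd.Timestamp(start)
    return [
        WeeklyCPUE(
            week_start=anchor + pd.Timedelta(days=7 * i),
            group=group,
            cpue=float(v),
            effort=NOMINAL_EFFORT,
        )
        for i, v in enumerate(values)
    ]


class TestWeekOfCohort:
    def test_first_week_of_cohort_year(self):
        assert week_of_cohort(pd.Timestamp("2014-08-01")) == 1
        assert week_of_cohort(pd.Timestamp("2014-08-08")) == 2

    def test_last_full_week(self):
        assert week_of_cohort(pd.Timestamp("2014-08-01") + pd.Timedelta(days=351)) == 51


class TestComputeWeeklyCpue:
    def test_nominal_effort_gives_raw_count(self):
        # 336 image pairs is exactly the nominal weekly effort
        rows = compute_weekly_cpue([record("2014-08-01", fish=12)])
        fish = next(r for r in rows if r.group == "fish")
        assert fish.cpue == pytest.approx(12.0)

    def test_half_effort_doubles_cpue(self):
        rows = compute_weekly_cpue([record("2014-08-01", effort=168, fish=6)])
        fish = next(r for r in rows if r.group == "fish")
        assert fish.cpue == pytest.approx(12.0)

    def test_zero_counts_give_zero_cpue_and_total(self):
        rows = compute_weekly_cpue([record("2014-08-01")])
        assert all(r.cpue == 0.0 for r in rows)
        total = next(r for r in rows if r.group == TOTAL)
        assert total.cpue == 0.0

    def test_total_is_sum_of_groups(self):
        rows = compute_weekly_cpue(
            [record("2014-08-01", effort=200, fish=3, jellyfish=5, pteropoda=1)]
        )
        total = next(r for r in rows if r.group == TOTAL)
        assert total.cpue == pytest.approx(
            sum(r.cpue for r in rows if r.group != TOTAL)
        )

    def test_effort_below_floor_is_missing_not_rescaled(self):
        rows = compute_weekly_cpue(
            [record("2014-08-01", effort=30, fish=2)], effort_floor=48
        )
        assert all(np.isnan(r.cpue) for r in rows)

    def test_duplicate_week_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_weekly_cpue([record("2014-08-01"), record("2014-08-01")])

    @settings(max_examples=30, deadline=None)
    @given(
        count=st.integers(0, 500),
        effort=st.integers(48, NOMINAL_EFFORT).filter(lambda e: e % 2 == 0),
    )
    def test_rescaling_invariance(self, count, effort):
        """Halving effort and counts together leaves CPUE unchanged."""
        full = compute_weekly_cpue([record("2014-08-01", effort=effort, fish=2 * count)])
        half = compute_weekly_cpue(
            [record("2014-08-01", effort=effort // 2, fish=count)], effort_floor=1
        )
        a = next(r for r in full if r.group == "fish").cpue
        b = next(r for r in half if r.group == "fish").cpue
        assert a == pytest.approx(b)


class TestTotalExcluding:
    def test_empty_exclusion_matches_total(self):
        records = [
            record("2014-08-01", fish=3, jellyfish=4),
            record("2014-08-08", effort=168, fish=1),
        ]
        full = [r for r in compute_weekly_cpue(records) if r.group == TOTAL]
        rebuilt = total_excluding(records, [])
        assert [r.cpue for r in rebuilt] == pytest.approx([r.cpue for r in full])

    def test_excluding_one_group_removes_its_contribution(self):
        records = [record("2014-08-01", fish=3, jellyfish=4)]
        rebuilt = total_excluding(records, ["jellyfish"])
        assert rebuilt[0].cpue == pytest.approx(3.0)

    def test_excluding_everything_is_an_error(self):
        with pytest.raises(ValueError, match="empty community"):
            total_excluding([record("2014-08-01")], BIOTIC_GROUPS)

    def test_unknown_exclusion_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            total_excluding([record("2014-08-01")], ["megafauna"])


class TestDetectBioticAnomalies:
    def test_all_weeks_inside_envelope(self):
        clim = flat_climatology(mean=5, lower=2, upper=8, unit="week_of_year")
        weekly = weekly_rows([5, 6, 4, 7])
        assert detect_biotic_anomalies(weekly, clim, TOTAL) == []

    def test_single_week_positive_anomaly(self):
        clim = flat_climatology(mean=5, lower=2, upper=8, unit="week_of_year")
        weekly = weekly_rows([5, 12.5, 6])  # upper 8 -> exceedance +4.5
        anomalies = detect_biotic_anomalies(weekly, clim, TOTAL)
        assert len(anomalies) == 1
        a = anomalies[0]
        assert (a.sign, a.duration_weeks) == (1, 1)
        assert a.magnitude == pytest.approx(4.5)

    def test_consecutive_negative_weeks_merge_and_sum(self):
        clim = flat_climatology(mean=5, lower=2, upper=8, unit="week_of_year")
        weekly = weekly_rows([5, 1.0, 0.0, 5])  # below lower 2 by 1.0 and 2.0
        anomalies = detect_biotic_anomalies(weekly, clim, TOTAL)
        assert len(anomalies) == 1
        a = anomalies[0]
        assert (a.sign, a.duration_weeks) == (-1, 2)
        assert a.magnitude == pytest.approx(-3.0)

    def test_non_consecutive_weeks_stay_separate(self):
        clim = flat_climatology(mean=5, lower=2, upper=8, unit="week_of_year")
        rows = weekly_rows([12, 5, 12])
        anomalies = detect_biotic_anomalies(rows, clim, TOTAL)
        assert len(anomalies) == 2

    def test_missing_weeks_break_runs(self):
        clim = flat_climatology(mean=5, lower=2, upper=8, unit="week_of_year")
        rows = weekly_rows([12, np.nan, 12])
        anomalies = detect_biotic_anomalies(rows, clim, TOTAL)
        assert len(anomalies) == 2

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_filter_then_merge_oracle(self, seed):
        """Detection equals per-week thresholding plus same-sign run merging."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 12, 30)
        values[rng.random(30) < 0.15] = np.nan
        clim = flat_climatology(mean=5, lower=2, upper=8, unit="week_of_year")
        rows = weekly_rows(values)
        anomalies = detect_biotic_anomalies(rows, clim, TOTAL)

        # oracle: filter weeks, then merge adjacent same-sign qualifying weeks
        marks = []
        for i, v in enumerate(values):
            if not np.isfinite(v):
                marks.append((i, 0, 0.0))
            elif v > 8:
                marks.append((i, 1, v - 8))
            elif v < 2:
                marks.append((i, -1, v - 2))
            else:
                marks.append((i, 0, 0.0))
        expected = []
        run = []
        for i, sign, exc in marks:
            if sign == 0:
                if run:
                    expected.append(run)
                    run = []
            elif run and run[-1][1] == sign and run[-1][0] == i - 1:
                run.append((i, sign, exc))
            else:
                if run:
                    expected.append(run)
                run = [(i, sign, exc)]
        if run:
            expected.append(run)
        got = [
            (week_of_cohort(a.week_start) - 1, a.sign, a.duration_weeks, a.magnitude)
            for a in anomalies
        ]
        want = [
            (r[0][0], r[0][1], len(r), pytest.approx(sum(x[2] for x in r)))
            for r in expected
        ]
        assert got == want


class TestGroupClimatology:
    def test_constant_weekly_series_collapses_envelope(self):
        rows = []
        for year in (2013, 2014, 2015):
            rows += weekly_rows([7.0] * 52, start=f"{year}-08-01")
        table = build_group_climatology(rows, TOTAL)
        np.testing.assert_allclose(table.mean, 7.0)
        np.testing.assert_allclose(table.lower, 7.0)
        np.testing.assert_allclose(table.upper, 7.0)


class TestMonthlySummary:
    def test_two_week_month_mean_and_sample_sd(self):
        rows = weekly_rows([10.0, 14.0], start="2014-09-03")
        frame = monthly_summary(rows)
        row = frame[(frame["month"] == "2014-09") & (frame["group"] == TOTAL)].iloc[0]
        assert row["mean_cpue"] == pytest.approx(12.0)
        assert row["sd_cpue"] == pytest.approx(np.std([10, 14], ddof=1))
        assert row["n_weeks"] == 2

    def test_single_week_month_sd_missing_by_default(self):
        rows = weekly_rows([10.0], start="2014-09-03")
        frame = monthly_summary(rows)
        row = frame.iloc[0]
        assert np.isnan(row["sd_cpue"])
        zero = monthly_summary(rows, single_week_sd="zero").iloc[0]
        assert zero["sd_cpue"] == 0.0

    def test_gap_months_reported_missing(self):
        rows = weekly_rows([10.0], start="2014-09-03") + weekly_rows(
            [12.0], start="2014-11-05"
        )
        frame = monthly_summary(rows)
        gap = frame[(frame["month"] == "2014-10") & (frame["group"] == TOTAL)].iloc[0]
        assert np.isnan(gap["mean_cpue"])
        assert gap["n_weeks"] == 0
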