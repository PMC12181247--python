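"""Cohort aggregation, rank regression and Mann–Kendall trend tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fjordlink.cohort_stats import (
    CohortSummary,
    assign_cohort_year,
    biotic_cohort_cumulative,
    cohort_cumulative,
    cohort_event_stats,
    cohort_year_end,
    cohort_year_start,
    coupling_analysis,
    mann_kendall,
    rank_cohorts,
    rank_regression,
)
from fjordlink.events import detect_events
from tests.conftest import flat_climatology, make_daily


def summaries_from(nets, variable="temperature", year0=2012):
    return [
        CohortSummary(
            cohort_year=year0 + i,
            variable=variable,
            positive_sum=max(v, 0.0),
            negative_sum=min(v, 0.0),
            n_anomaly_days=1,
        )
        for i, v in enumerate(nets)
    ]


class TestCohortCalendar:
    @pytest.mark.parametrize(
        ("date", "cohort"),
        [
            ("2014-08-01", 2014),  # first day of the 2014 cohort year
            ("2015-07-31", 2014),  # last day of the 2014 cohort year
            ("2015-08-01", 2015),  # boundary rollover
            ("2014-12-31", 2014),
            ("2015-01-01", 2014),
        ],
    )
    def test_assign_cohort_year(self, date, cohort):
        assert assign_cohort_year(pd.Timestamp(date)) == cohort

    def test_cohort_span_endpoints(self):
        assert cohort_year_start(2014) == pd.Timestamp("2014-08-01")
        assert cohort_year_end(2014) == pd.Timestamp("2015-07-31")


class TestCohortCumulative:
    def test_no_anomalies_gives_zero_sums(self, flat_clim):
        series = make_daily(np.zeros(400), start="2014-08-01")
        summaries = cohort_cumulative([], series, flat_clim)
        assert all(s.positive_sum == 0 and s.negative_sum == 0 for s in summaries)
        assert all(s.net_sum == 0 for s in summaries)

    def test_two_positive_events_sum_directly(self, flat_clim):
        # events of +5.0 and +2.5 mean-baseline day-degrees in one cohort
        values = np.zeros(300)
        values[10:15] = 1.0 + 1e-12  # 5 days, ~1.0 above mean 0 -> +5.0
        values[100:105] = 0.5 + 1e-12
        clim = flat_climatology(mean=0.0, lower=-0.2, upper=0.2)
        series = make_daily(values, start="2014-08-01")
        events = detect_events(series, clim, min_duration=5)
        assert len(events) == 2
        summaries = cohort_cumulative(events, series, clim, baseline="mean")
        s2014 = next(s for s in summaries if s.cohort_year == 2014)
        assert s2014.positive_sum == pytest.approx(7.5)
        assert s2014.n_anomaly_days == 10

    def test_event_straddling_cohort_boundary_splits_by_day(self):
        # event spanning 30 Jul - 03 Aug: 2 days to cohort Y-1, 3 days to Y
        clim = flat_climatology(mean=0.0, lower=-0.2, upper=0.2)
        dates = pd.date_range("2015-07-01", "2015-09-01", freq="D")
        values = np.zeros(len(dates))
        sel = (dates >= "2015-07-30") & (dates <= "2015-08-03")
        values[sel] = 2.0
        series = make_daily(values, start="2015-07-01")
        series.dates = dates
        events = detect_events(series, clim, min_duration=5)
        assert len(events) == 1
        summaries = cohort_cumulative(events, series, clim, baseline="mean")
        by_year = {s.cohort_year: s for s in summaries}
        assert by_year[2014].positive_sum == pytest.approx(4.0)  # 2 days x 2.0
        assert by_year[2015].positive_sum == pytest.approx(6.0)  # 3 days x 2.0
        # splitting conserves the unsplit total
        total = sum(s.positive_sum for s in summaries)
        assert total == pytest.approx(events[0].day_degrees)

    def test_threshold_baseline_uses_crossed_envelope(self):
        clim = flat_climatology(mean=0.0, lower=-0.5, upper=0.5)
        values = np.zeros(300)
        values[10:15] = 2.0
        series = make_daily(values, start="2014-08-01")
        events = detect_events(series, clim)
        summaries = cohort_cumulative(events, series, clim, baseline="threshold")
        s = next(s for s in summaries if s.cohort_year == 2014)
        assert s.positive_sum == pytest.approx(5 * 1.5)


class TestRankCohorts:
    def test_monotone_keys_get_identity_ranks(self):
        years, ranks = rank_cohorts(summaries_from([-271, -50, 10, 200]))
        assert years == [2012, 2013, 2014, 2015]
        np.testing.assert_allclose(ranks, [1, 2, 3, 4])

    def test_ties_receive_average_ranks(self):
        _, ranks = rank_cohorts(summaries_from([5, 5, 1]))
        np.testing.assert_allclose(ranks, [2.5, 2.5, 1])

    def test_total_tie_gives_midrank(self):
        _, ranks = rank_cohorts(summaries_from([3, 3, 3, 3, 3]))
        np.testing.assert_allclose(ranks, 3.0)

    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            rank_cohorts(summaries_from([1.0]))


class TestRankRegression:
    def test_reference_rank_pair_statistics(self):
        """Length-8 rank pairs with squared-difference sum 16 reproduce the
        published all-groups coupling statistics at two decimals."""
        x = np.arange(1, 9)
        y = np.array([3, 4, 1, 2, 5, 6, 7, 8])
        assert ((x - y) ** 2).sum() == 16
        res = rank_regression(x, y)
        assert round(res.F, 2) == 11.41
        assert round(res.slope, 2) == 0.81
        assert round(res.t_value, 2) == 3.38
        assert res.p_value < 0.05

    def test_reference_pair_with_squared_difference_18(self):
        x = np.arange(1, 9)
        y = np.array([4, 2, 3, 1, 5, 6, 7, 8])
        assert ((x - y) ** 2).sum() == 18
        res = rank_regression(x, y)
        assert round(res.F, 2) == 9.68
        assert round(res.adj_r2, 2) == 0.55

    def test_perfect_fit_convention(self):
        x = np.arange(1, 9)
        res = rank_regression(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert math.isinf(res.F) and res.p_value == 0.0

    def test_antitone_slope(self):
        x = np.arange(1, 9)
        res = rank_regression(x, x[::-1])
        assert res.slope == pytest.approx(-1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rank_regression([1, 2], [1, 2])
        with pytest.raises(ValueError):
            rank_regression([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            rank_regression([2, 2, 2], [1, 2, 3])

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_slope_identity_for_untied_length8_ranks(self, seed):
        """slope = 1 - sum(d^2)/84 for untied length-8 rank vectors."""
        rng = np.random.default_rng(seed)
        x = np.arange(1, 9)
        y = rng.permutation(x)
        d2 = float(((x - y) ** 2).sum())
        res = rank_regression(x, y)
        assert res.slope == pytest.approx(1.0 - d2 / 84.0)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 12))
    def test_slope_equals_spearman_and_f_identity(self, seed, n):
        """Rank-OLS slope equals Spearman rho; F = (n-2) r^2 / (1 - r^2)."""
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1, n + 1))
        y = rng.permutation(np.arange(1, n + 1))
        res = rank_regression(x, y)
        rho = stats.spearmanr(x, y).statistic
        assert res.slope == pytest.approx(rho, abs=1e-12)
        if res.r2 < 1.0:
            assert res.F == pytest.approx((n - 2) * res.r2 / (1 - res.r2))
        assert res.F == pytest.approx(res.t_value**2)
        assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * (n - 1) / (n - 2))


class TestMannKendall:
    def test_monotone_increasing(self):
        res = mann_kendall([1, 2, 3, 4])
        assert res.tau == pytest.approx(1.0)
        assert res.s_statistic == 6

    def test_monotone_decreasing(self):
        assert mann_kendall([4, 3, 2, 1]).tau == pytest.approx(-1.0)

    def test_mixed_sequence_pair_count(self):
        # pairs of (3,1,2,4): 4 concordant, 2 discordant -> S=2, tau=1/3
        res = mann_kendall([3, 1, 2, 4])
        assert res.s_statistic == 2
        assert res.tau == pytest.approx(1 / 3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1, 2])
        with pytest.raises(ValueError):
            mann_kendall([np.nan, np.nan, np.nan])

    @settings(max_examples=60, deadline=None)
    @given(
        values=st.lists(st.integers(0, 6), min_size=3, max_size=8),
    )
    def test_s_and_tau_match_exhaustive_pair_enumeration(self, values):
        x = np.array(values, dtype=float)
        s = sum(
            np.sign(x[j] - x[i]) for i in range(len(x)) for j in range(i + 1, len(x))
        )
        res = mann_kendall(x)
        assert res.s_statistic == int(s)
        # tau-b against time (no ties in the time axis)
        tau_ref = stats.kendalltau(np.arange(len(x)), x).statistic
        if np.isnan(tau_ref):  # all values tied
            assert res.tau == 0.0
        else:
            assert res.tau == pytest.approx(tau_ref)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_p_matches_permutation_enumeration(self, n):
        """For tie-free series the exact p equals full enumeration of S."""
        rng = np.random.default_rng(42)
        x = rng.permutation(np.arange(1, n + 1)).astype(float)
        res = mann_kendall(x)

        def s_of(seq):
            return sum(
                np.sign(seq[j] - seq[i])
                for i in range(n)
                for j in range(i + 1, n)
            )

        all_s = [s_of(p) for p in itertools.permutations(x)]
        s_obs = abs(res.s_statistic)
        if s_obs == 0:
            expected = 1.0
        else:
            expected = 2 * np.mean([s >= s_obs for s in all_s])
        assert res.p_value == pytest.approx(min(expected, 1.0))


class TestCohortEventStats:
    def test_frequency_and_intensity_attribution(self, flat_clim):
        values = np.zeros(800)
        values[10:20] = 2.0  # positive event in cohort 2014
        values[400:408] = -2.0  # negative event in cohort 2015
        series = make_daily(values, start="2014-08-01")
        events = detect_events(series, flat_clim)
        table = cohort_event_stats(events, [2014, 2015, 2016])
        assert table.loc[2014, "n_events_positive"] == 1
        assert table.loc[2015, "n_events_negative"] == 1
        assert table.loc[2016, "n_events_total"] == 0
        assert table.loc[2015, "intensity_negative"] == pytest.approx(16.0)


class TestCouplingAnalysis:
    @staticmethod
    def _records(seed=0, beta=0.0):
        import fjordlink.synthetic as syn

        cfg = syn.demo_scenario(seed=seed, coupling_beta=beta)
        return syn.generate_scenario(cfg)

    def test_empty_exclusion_equals_all_groups(self):
        ds = self._records(seed=3)
        abiotic = summaries_from([-20, -5, 3, 10, 12, -8, 6, 1])
        a = coupling_analysis(abiotic, ds.survey, exclude_groups=[])
        b = coupling_analysis(abiotic, ds.survey)
        assert a == b

    def test_excluding_all_groups_fails(self):
        from fjordlink.series_io import BIOTIC_GROUPS

        ds = self._records(seed=3)
        abiotic = summaries_from([-20, -5, 3, 10, 12, -8, 6, 1])
        with pytest.raises(ValueError, match="empty community"):
            coupling_analysis(abiotic, ds.survey, exclude_groups=BIOTIC_GROUPS)

    def test_cohort_set_mismatch_detected(self):
        ds = self._records(seed=3)
        abiotic = summaries_from([-20, -5, 3])  # 2012-2014 only vs 8 survey years
        with pytest.raises(ValueError, match="cohort"):
            coupling_analysis(abiotic, ds.survey)
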