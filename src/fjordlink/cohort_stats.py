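"""Cohort-year aggregation and rank-based coupling statistics.

Anomaly events are accumulated into cohort years (01 Aug – 31 Jul) as
cumulative day-degrees; the per-cohort net sums are rank-transformed and
coupled by ordinary least squares on the ranks.  Rank transformation tames
the skew inherent in anomaly sums (positive abundance anomalies are
unbounded, negative ones cannot fall below zero), at the cost of discarding
metric distance between years.

For untied rank vectors the rank-OLS slope equals the Spearman rank
correlation of the underlying keys, and for n = 8 cohort years reduces to
the classical identity slope = 1 − Σd²/84 where d are the paired rank
differences.  The slope's F statistic has (1, n−2) degrees of freedom and
equals t².

Mann–Kendall trend tests ask whether anomaly frequency or intensity drifts
across cohort years: S = Σ_{i<j} sign(x_j − x_i), tau = S normalized with
tie correction, and a two-sided p from the exact null distribution of S
(n ≤ 10, no ties) or the tie-corrected normal approximation with
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climatology import ClimatologyTable
from .cohort_calendar import assign_cohort_year, cohort_year_end, cohort_year_start
from .events import POSITIVE, AnomalyEvent
from .series_io import BIOTIC_GROUPS, TOTAL, DailySeries, SurveyRecord

__all__ = [
    "assign_cohort_year",
    "cohort_year_start",
    "cohort_year_end",
    "CohortSummary",
    "TrendResult",
    "RankRegressionResult",
    "cohort_cumulative",
    "biotic_cohort_cumulative",
    "rank_cohorts",
    "rank_regression",
    "mann_kendall",
    "cohort_event_stats",
    "coupling_analysis",
    "group_coupling_table",
    "summaries_frame",
]


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    """Cumulative anomaly sums for one variable in one cohort year."""

    cohort_year: int
    variable: str
    positive_sum: float  # >= 0; unit·days (abiotic) or CPUE-sum (biotic)
    negative_sum: float  # <= 0
    n_anomaly_days: int  # anomalous days (abiotic) or weeks (biotic)

    @property
    def net_sum(self) -> float:
        return self.positive_sum + self.negative_sum


@dataclass(frozen=True)
class TrendResult:
    """Mann–Kendall trend test output."""

    tau: float
    s_statistic: int
    p_value: float
    n: int


@dataclass(frozen=True)
class RankRegressionResult:
    """OLS of y-ranks on x-ranks with slope inference."""

    slope: float
    intercept: float
    t_value: float
    F: float  # = t² with df (1, n-2)
    r2: float
    adj_r2: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def _cohort_range(cohorts: Sequence[int] | None, dates: pd.DatetimeIndex) -> list[int]:
    if cohorts is not None:
        return sorted(int(c) for c in cohorts)
    first = assign_cohort_year(dates[0])
    last = assign_cohort_year(dates[-1])
    return list(range(first, last + 1))


def cohort_cumulative(
    events: Sequence[AnomalyEvent],
    series: DailySeries,
    clim: ClimatologyTable,
    baseline: str = "mean",
    cohorts: Sequence[int] | None = None,
) -> list[CohortSummary]:
    """Accumulate abiotic event day-degrees into cohort years.

    Events straddling 31 July are split by day, so each anomalous day is
    attributed to exactly one cohort year and the split sums conserve the
    unsplit total.  Cohorts without anomalies appear with zero sums.
    """
    mean, lower, upper = clim.curves_for_dates(series.dates)
    pos: dict[int, float] = {}
    neg: dict[int, float] = {}
    days: dict[int, int] = {}
    cohort_of_day = np.array([assign_cohort_year(d) for d in series.dates])

    for event in events:
        sel = (series.dates >= event.start) & (series.dates <= event.end)
        idx = np.flatnonzero(sel)
        for i in idx:
            v = series.values[i]
            if not np.isfinite(v):
                continue
            if baseline == "mean":
                contrib = v - mean[i]
            elif baseline == "threshold":
                if event.sign == POSITIVE:
                    contrib = max(v - upper[i], 0.0)
                else:
                    contrib = min(v - lower[i], 0.0)
            else:
                raise ValueError(f"unknown baseline {baseline!r}")
            c = int(cohort_of_day[i])
            if event.sign == POSITIVE:
                pos[c] = pos.get(c, 0.0) + contrib
            else:
                neg[c] = neg.get(c, 0.0) + contrib
            days[c] = days.get(c, 0) + 1

    out = []
    for c in _cohort_range(cohorts, series.dates):
        out.append(
            CohortSummary(
                cohort_year=c,
                variable=series.variable,
                positive_sum=pos.get(c, 0.0),
                negative_sum=neg.get(c, 0.0),
                n_anomaly_days=days.get(c, 0),
            )
        )
    return out


def biotic_cohort_cumulative(
    weekly,
    clim: ClimatologyTable,
    group: str = TOTAL,
    min_duration_weeks: int = 1,
    cohorts: Sequence[int] | None = None,
) -> list[CohortSummary]:
    """Accumulate weekly biotic exceedances into cohort years.

    Weeks never straddle the cohort boundary (the weekly grid is anchored
    at 01 August), so each anomalous week belongs to exactly one cohort.
    With ``min_duration_weeks > 1`` only weeks inside retained anomaly runs
    contribute.
    """
    from .biotic import detect_biotic_anomalies, weekly_exceedance  # circular-safe

    exc = weekly_exceedance(weekly, clim, group)
    if min_duration_weeks > 1:
        keep: set[pd.Timestamp] = set()
        for anomaly in detect_biotic_anomalies(weekly, clim, group, min_duration_weeks):
            for k in range(anomaly.duration_weeks):
                keep.add(anomaly.week_start + pd.Timedelta(days=7 * k))
        exc = exc[exc["week_start"].isin(keep)]

    pos: dict[int, float] = {}
    neg: dict[int, float] = {}
    weeks: dict[int, int] = {}
    for _, row in exc.iterrows():
        if row["sign"] == 0:
            continue
        c = assign_cohort_year(row["week_start"])
        if row["sign"] > 0:
            pos[c] = pos.get(c, 0.0) + float(row["exceedance"])
        else:
            neg[c] = neg.get(c, 0.0) + float(row["exceedance"])
        weeks[c] = weeks.get(c, 0) + 1

    all_weeks = pd.DatetimeIndex([w.week_start for w in weekly])
    out = []
    for c in _cohort_range(cohorts, all_weeks.sort_values()):
        out.append(
            CohortSummary(
                cohort_year=c,
                variable=f"cpue:{group}",
                positive_sum=pos.get(c, 0.0),
                negative_sum=neg.get(c, 0.0),
                n_anomaly_days=weeks.get(c, 0),
            )
        )
    return out


def summaries_frame(summaries: Iterable[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cohort_year": s.cohort_year,
                "variable": s.variable,
                "positive_sum": s.positive_sum,
                "negative_sum": s.negative_sum,
                "net_sum": s.net_sum,
                "n_anomaly_days": s.n_anomaly_days,
            }
            for s in summaries
        ],
        columns=[
            "cohort_year",
            "variable",
            "positive_sum",
            "negative_sum",
            "net_sum",
            "n_anomaly_days",
        ],
    )


# ---------------------------------------------------------------------------
# ranking and rank regression
# ---------------------------------------------------------------------------

def rank_cohorts(
    summaries: Sequence[CohortSummary],
    key: str = "net_sum",
) -> tuple[list[int], np.ndarray]:
    """Ranks 1..n ascending by the chosen key; ties get average ranks.

    The default ``net_sum`` key orders cohorts along a single axis from the
    most anomalous cold spell (lowest rank) to the most anomalous heat wave
    (highest rank).  ``positive_sum``/``negative_sum`` are available as
    alternative keys.
    """
    if len(summaries) < 2:
        raise ValueError("ranking requires at least two cohorts")
    ordered = sorted(summaries, key=lambda s: s.cohort_year)
    keys = np.array([getattr(s, key) for s in ordered], dtype=float)
    ranks = stats.rankdata(keys, method="average")
    return [s.cohort_year for s in ordered], ranks


def rank_regression(
    x_ranks: Sequence[float],
    y_ranks: Sequence[float],
) -> RankRegressionResult:
    """Ordinary least squares of y-ranks on x-ranks with slope inference.

    The slope F statistic has (1, n−2) degrees of freedom; p is two-sided.
    A perfect fit (zero residual variance) reports F and |t| as +infinity
    with p = 0 by convention.
    """
    x = np.asarray(x_ranks, dtype=float)
    y = np.asarray(y_ranks, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rank vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("rank regression requires n >= 3")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("zero variance in x ranks")

    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    df = n - 2

    if ss_tot == 0.0:
        # all y-ranks tied: no association to quantify
        return RankRegressionResult(
            slope=0.0, intercept=intercept, t_value=0.0, F=0.0,
            r2=0.0, adj_r2=0.0, p_value=1.0, n=n,
        )
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    if ss_res <= 1e-12 * ss_tot:
        t = math.copysign(math.inf, slope)
        return RankRegressionResult(
            slope=slope, intercept=intercept, t_value=t, F=math.inf,
            r2=1.0, adj_r2=1.0, p_value=0.0, n=n,
        )
    se = math.sqrt(ss_res / df / sxx)
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return RankRegressionResult(
        slope=slope,
        intercept=intercept,
        t_value=t,
        F=t * t,
        r2=r2,
        adj_r2=adj_r2,
        p_value=p,
        n=n,
    )


# ---------------------------------------------------------------------------
# Mann–Kendall trend test
# ---------------------------------------------------------------------------

def _exact_s_tail(n: int, s_abs: int) -> float:
    """P(S >= s_abs) under the exact tie-free null for series length n.

    For distinct values S = n(n-1)/2 − 2·inv where inv is the number of
    discordant pairs (inversions) of a uniformly random permutation; the
    inversion-count distribution is the coefficient sequence of
    ∏_{k=1..n} (1 + x + … + x^{k−1}).
    """
    counts = np.array([1.0])
    for k in range(2, n + 1):
        counts = np.convolve(counts, np.ones(k))
    total = counts.sum()
    n0 = n * (n - 1) // 2
    # S >= s_abs  <=>  inv <= (n0 - s_abs) / 2
    max_inv = (n0 - s_abs) // 2
    return float(counts[: max_inv + 1].sum() / total)


def mann_kendall(series: Sequence[float]) -> TrendResult:
    """Mann–Kendall trend test on an ordered numeric sequence.

    S = Σ_{i<j} sign(x_j − x_i); tau is tie-corrected (equivalent to
    Kendall's tau-b against time); the two-sided p comes from the exact
    enumeration of the tie-free null for n ≤ 10, otherwise from the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Mann–Kendall requires n >= 3 non-missing values")

    diff = np.sign(np.subtract.outer(x, x))  # diff[i, j] = sign(x_i - x_j)
    s = int(np.triu(-diff, k=1).sum())  # Σ_{i<j} sign(x_j - x_i)

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    n0 = n * (n - 1) // 2
    tie_pairs = int((ties * (ties - 1) // 2).sum())
    denom = math.sqrt(n0 - tie_pairs) * math.sqrt(n0)
    tau = s / denom if denom > 0 else 0.0

    if n <= 10 and len(ties) == 0:
        p = 2.0 * _exact_s_tail(n, abs(s)) if s != 0 else 1.0
        p = min(p, 1.0)
    else:
        var_s = (
            n * (n - 1) * (2 * n + 5) - int((ties * (ties - 1) * (2 * ties + 5)).sum())
        ) / 18.0
        if var_s <= 0:
            p = 1.0
        else:
            z = (s - math.copysign(1, s)) / math.sqrt(var_s) if s != 0 else 0.0
            p = 2.0 * float(stats.norm.sf(abs(z)))
    return TrendResult(tau=float(tau), s_statistic=s, p_value=float(p), n=n)


def cohort_event_stats(
    events: Sequence[AnomalyEvent],
    cohorts: Sequence[int],
    baseline: str = "mean",
) -> pd.DataFrame:
    """Per-cohort anomaly frequency and intensity series for trend testing.

    Events straddling 31 July count toward the cohort containing their
    start date for frequency; intensity uses |day-degrees| of the chosen
    baseline, attributed the same way.  One column per sign plus totals.
    """
    cohorts = sorted(int(c) for c in cohorts)
    cols = {
        "n_events_total": {c: 0 for c in cohorts},
        "n_events_positive": {c: 0 for c in cohorts},
        "n_events_negative": {c: 0 for c in cohorts},
        "intensity_positive": {c: 0.0 for c in cohorts},
        "intensity_negative": {c: 0.0 for c in cohorts},
    }
    for event in events:
        c = assign_cohort_year(event.start)
        if c not in cols["n_events_total"]:
            continue
        dd = event.day_degrees if baseline == "mean" else event.day_degrees_threshold
        cols["n_events_total"][c] += 1
        if event.sign == POSITIVE:
            cols["n_events_positive"][c] += 1
            cols["intensity_positive"][c] += abs(dd)
        else:
            cols["n_events_negative"][c] += 1
            cols["intensity_negative"][c] += abs(dd)
    return pd.DataFrame({k: [v[c] for c in cohorts] for k, v in cols.items()},
                        index=pd.Index(cohorts, name="cohort_year"))


# ---------------------------------------------------------------------------
# abiotic–biotic coupling
# ---------------------------------------------------------------------------

def coupling_analysis(
    abiotic_summaries: Sequence[CohortSummary],
    records: Sequence[SurveyRecord],
    exclude_groups: Iterable[str] = (),
    group: str = TOTAL,
    ranking_key: str = "net_sum",
    min_duration_weeks: int = 1,
    window_halfwidth_weeks: int = 1,
    percentile_pair: tuple[float, float] = (0.1, 0.9),
    effort_floor: int | None = None,
) -> RankRegressionResult:
    """Rank-regress biotic cohort anomaly sums on abiotic cohort sums.

    The biotic side is recomputed from the weekly survey records: weekly
    CPUE (for ``group``, or the TOTAL rebuilt without ``exclude_groups``),
    weekly climatology, weekly exceedances, cohort sums, ranks.  The cohort
    sets of the two sides must match.
    """
    from . import biotic  # circular-safe

    if effort_floor is None:
        effort_floor = biotic.DEFAULT_EFFORT_FLOOR
    exclude = list(exclude_groups)
    if exclude and group != TOTAL:
        raise ValueError("group exclusion applies only to the TOTAL series")
    if group == TOTAL:
        weekly = biotic.total_excluding(records, exclude, effort_floor=effort_floor)
    else:
        if group not in BIOTIC_GROUPS:
            raise ValueError(f"unknown biotic group {group!r}")
        weekly = [
            w
            for w in biotic.compute_weekly_cpue(records, effort_floor=effort_floor)
            if w.group == group
        ]

    clim = biotic.build_group_climatology(
        weekly,
        group,
        window_halfwidth=window_halfwidth_weeks,
        percentile_pair=percentile_pair,
    )
    cohorts = sorted(s.cohort_year for s in abiotic_summaries)
    survey_cohorts = sorted({assign_cohort_year(w.week_start) for w in weekly})
    if survey_cohorts != cohorts:
        raise ValueError(
            "abiotic and biotic cohort-year sets differ: "
            f"{cohorts} vs {survey_cohorts}"
        )
    biotic_summaries = biotic_cohort_cumulative(
        weekly, clim, group, min_duration_weeks=min_duration_weeks, cohorts=cohorts
    )

    _, x_ranks = rank_cohorts(abiotic_summaries, key=ranking_key)
    _, y_ranks = rank_cohorts(biotic_summaries, key=ranking_key)
    return rank_regression(x_ranks, y_ranks)


def group_coupling_table(
    abiotic_summaries: Sequence[CohortSummary],
    records: Sequence[SurveyRecord],
    **kwargs,
) -> pd.DataFrame:
    """Per-configuration rank regressions: TOTAL, TOTAL without jellyfish,
    and each biotic group separately (one row per configuration)."""
    configs: list[tuple[str, Mapping]] = [
        ("all_groups", {"group": TOTAL}),
        ("without_jellyfish", {"group": TOTAL, "exclude_groups": ["jellyfish"]}),
    ]
    configs += [(g, {"group": g}) for g in BIOTIC_GROUPS]

    rows = []
    for name, cfg in configs:
        res = coupling_analysis(abiotic_summaries, records, **cfg, **kwargs)
        rows.append(
            {
                "configuration": name,
                "n": res.n,
                "slope": res.slope,
                "intercept": res.intercept,
                "t_value": res.t_value,
                "F": res.F,
                "r2": res.r2,
                "adj_r2": res.adj_r2,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
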