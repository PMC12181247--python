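"""Weekly CPUE standardization and biotic anomaly detection.

The stereoscopic observatory nominally yields 336 image pairs per week
(2 images/hour x 24 h x 7 days).  Weekly organism counts are standardized
to catch-per-unit-effort (CPUE) at that nominal effort:
``cpue = count * 336 / effort``.  Weeks whose analysed effort falls below a
floor (default 48 image pairs, one full day) are marked missing rather than
rescaled — rescaling from a sliver of effort would manufacture precision.

Biotic anomalies mirror the abiotic detector at weekly resolution: a week
qualifies when its CPUE lies outside the weekly climatological percentile
envelope, and consecutive qualifying weeks of equal sign merge into one
anomaly.  The weekly grid is anchored at 01 August of each cohort year so
that week boundaries align with cohort years; weeks 1..52 cover the year
and the 1-2 remaining days form a truncated week 53.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .climatology import ClimatologyTable, build_weekly_climatology
from .cohort_calendar import assign_cohort_year, cohort_year_start
from .series_io import BIOTIC_GROUPS, TOTAL, SurveyRecord

NOMINAL_EFFORT = 336  # image pairs per week: 2/hour * 24 h * 7 days
DEFAULT_EFFORT_FLOOR = 48  # one full day of image pairs


@dataclass(frozen=True)
class WeeklyCPUE:
    """Effort-standardized weekly abundance for one group (or TOTAL)."""

    week_start: pd.Timestamp
    group: str
    cpue: float  # organisms per 336 image pairs; NaN when effort below floor
    effort: int  # image pairs actually analysed


@dataclass(frozen=True)
class BioticAnomaly:
    """A run of weeks with CPUE outside the climatological envelope."""

    group: str
    week_start: pd.Timestamp  # first week of the run
    sign: int  # +1 above upper, -1 below lower
    duration_weeks: int
    magnitude: float  # signed sum of weekly exceedances beyond the envelope


def week_of_cohort(week_start: pd.Timestamp) -> int:
    """1-based week index of a week-start date on the cohort-anchored grid."""
    cohort = assign_cohort_year(week_start)
    offset = (pd.Timestamp(week_start) - cohort_year_start(cohort)).days
    unit = offset // 7 + 1
    if not 1 <= unit <= 53:
        raise ValueError(f"week_start {week_start} outside the cohort weekly grid")
    return int(unit)


def compute_weekly_cpue(
    records: Sequence[SurveyRecord],
    nominal_effort: int = NOMINAL_EFFORT,
    effort_floor: int = DEFAULT_EFFORT_FLOOR,
) -> list[WeeklyCPUE]:
    """Standardize weekly counts to CPUE at the nominal effort.

    Emits one row per (week, group) plus a TOTAL row per week.  Weeks with
    effort below ``effort_floor`` are marked missing (NaN CPUE) rather than
    rescaled.  Duplicate weeks raise.
    """
    seen: set[pd.Timestamp] = set()
    out: list[WeeklyCPUE] = []
    for rec in sorted(records, key=lambda r: r.week_start):
        if rec.week_start in seen:
            raise ValueError(f"duplicate survey week {rec.week_start.date()}")
        seen.add(rec.week_start)
        usable = rec.image_pairs >= effort_floor and rec.image_pairs > 0
        total = 0.0
        for group in BIOTIC_GROUPS:
            count = int(rec.counts.get(group, 0))
            if count < 0:
                raise ValueError(f"negative count for {group} in week {rec.week_start}")
            cpue = count * nominal_effort / rec.image_pairs if usable else np.nan
            total += cpue
            out.append(
                WeeklyCPUE(
                    week_start=rec.week_start,
                    group=group,
                    cpue=float(cpue),
                    effort=rec.image_pairs,
                )
            )
        out.append(
            WeeklyCPUE(
                week_start=rec.week_start,
                group=TOTAL,
                cpue=float(total),
                effort=rec.image_pairs,
            )
        )
    return out


def total_excluding(
    records: Sequence[SurveyRecord],
    exclude_groups: Iterable[str] = (),
    nominal_effort: int = NOMINAL_EFFORT,
    effort_floor: int = DEFAULT_EFFORT_FLOOR,
) -> list[WeeklyCPUE]:
    """Rebuild the TOTAL weekly CPUE series with some groups removed.

    Exclusion happens on the weekly counts, before anomaly detection:
    anomalies are nonlinear in the climatological threshold, so subtracting
    a group's anomalies from the TOTAL anomalies would not be equivalent.
    """
    exclude = {g.strip().lower() for g in exclude_groups}
    unknown = exclude - set(BIOTIC_GROUPS)
    if unknown:
        raise ValueError(f"unknown groups in exclusion set: {sorted(unknown)}")
    kept = [g for g in BIOTIC_GROUPS if g not in exclude]
    if not kept:
        raise ValueError("excluding every biotic group leaves an empty community")

    out: list[WeeklyCPUE] = []
    for rec in sorted(records, key=lambda r: r.week_start):
        usable = rec.image_pairs >= effort_floor and rec.image_pairs > 0
        count = sum(int(rec.counts.get(g, 0)) for g in kept)
        cpue = count * nominal_effort / rec.image_pairs if usable else np.nan
        out.append(
            WeeklyCPUE(
                week_start=rec.week_start,
                group=TOTAL,
                cpue=float(cpue),
                effort=rec.image_pairs,
            )
        )
    return out


def cpue_frame(weekly: Iterable[WeeklyCPUE]) -> pd.DataFrame:
    """Tabulate weekly CPUE rows for CSV export or internal use."""
    return pd.DataFrame(
        [
            {
                "week_start": w.week_start,
                "group": w.group,
                "effort": w.effort,
                "cpue": w.cpue,
            }
            for w in weekly
        ]
    )


def group_series(weekly: Sequence[WeeklyCPUE], group: str) -> list[WeeklyCPUE]:
    return [w for w in weekly if w.group == group]


def build_group_climatology(
    weekly: Sequence[WeeklyCPUE],
    group: str,
    window_halfwidth: int = 1,
    smooth_span: int = 0,
    percentile_pair: tuple[float, float] = (0.1, 0.9),
    estimator: str = "linear",
) -> ClimatologyTable:
    """Week-of-year climatology of one group's CPUE across cohort years."""
    rows = group_series(weekly, group)
    if not rows:
        raise ValueError(f"no weekly CPUE rows for group {group!r}")
    units = [week_of_cohort(w.week_start) for w in rows]
    years = [assign_cohort_year(w.week_start) for w in rows]
    values = [w.cpue for w in rows]
    return build_weekly_climatology(
        units,
        years,
        values,
        window_halfwidth=window_halfwidth,
        smooth_span=smooth_span,
        percentile_pair=percentile_pair,
        estimator=estimator,
        variable=f"cpue:{group}",
    )


def weekly_exceedance(
    weekly: Sequence[WeeklyCPUE],
    clim: ClimatologyTable,
    group: str,
) -> pd.DataFrame:
    """Per-week signed exceedance beyond the crossed envelope for one group.

    Returns a frame with columns week_start, sign (+1/-1/0), exceedance
    (0 inside the envelope, NaN rows dropped for missing weeks).
    """
    if clim.unit != "week_of_year":
        raise ValueError("biotic detection requires a week-of-year climatology")
    rows = sorted(group_series(weekly, group), key=lambda w: w.week_start)
    records = []
    for w in rows:
        if not np.isfinite(w.cpue):
            continue
        _, lower, upper = clim.curves_at(np.array([week_of_cohort(w.week_start)]))
        if w.cpue > upper[0]:
            sign, exc = 1, w.cpue - upper[0]
        elif w.cpue < lower[0]:
            sign, exc = -1, w.cpue - lower[0]
        else:
            sign, exc = 0, 0.0
        records.append({"week_start": w.week_start, "sign": sign, "exceedance": exc})
    return pd.DataFrame(records, columns=["week_start", "sign", "exceedance"])


def detect_biotic_anomalies(
    weekly: Sequence[WeeklyCPUE],
    clim: ClimatologyTable,
    group: str,
    min_duration_weeks: int = 1,
) -> list[BioticAnomaly]:
    """Detect weekly biotic anomalies for one group.

    A week qualifies when its CPUE lies strictly outside the envelope;
    consecutive qualifying weeks (7 days apart) of equal sign merge into one
    anomaly whose magnitude is the signed sum of weekly exceedances.
    Missing weeks break runs.
    """
    if min_duration_weeks < 1:
        raise ValueError("min_duration_weeks must be >= 1")
    exc = weekly_exceedance(weekly, clim, group)
    anomalies: list[BioticAnomaly] = []
    run: list[tuple[pd.Timestamp, int, float]] = []

    def flush() -> None:
        if len(run) >= min_duration_weeks:
            anomalies.append(
                BioticAnomaly(
                    group=group,
                    week_start=run[0][0],
                    sign=run[0][1],
                    duration_weeks=len(run),
                    magnitude=float(sum(r[2] for r in run)),
                )
            )
        run.clear()

    prev_week: pd.Timestamp | None = None
    for _, row in exc.iterrows():
        consecutive = (
            prev_week is not None and (row["week_start"] - prev_week).days == 7
        )
        if row["sign"] == 0:
            flush()
        else:
            if run and (run[-1][1] != row["sign"] or not consecutive):
                flush()
            run.append((row["week_start"], int(row["sign"]), float(row["exceedance"])))
        prev_week = row["week_start"]
    flush()
    return anomalies


def anomalies_frame(anomalies: Iterable[BioticAnomaly]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": a.group,
                "week_start": a.week_start.strftime("%Y-%m-%d"),
                "sign": "positive" if a.sign > 0 else "negative",
                "duration_weeks": a.duration_weeks,
                "magnitude": a.magnitude,
            }
            for a in anomalies
        ],
        columns=["group", "week_start", "sign", "duration_weeks", "magnitude"],
    )


def monthly_summary(
    weekly: Sequence[WeeklyCPUE],
    single_week_sd: str = "missing",
) -> pd.DataFrame:
    """Monthly mean and SD of weekly CPUE per group, weeks as replicates.

    Weeks are assigned to months by their start date.  Months inside the
    surveyed span with no usable weeks appear with missing mean/SD.  The SD
    of a single-week month is missing by default (``single_week_sd="zero"``
    reports 0 instead).
    """
    frame = cpue_frame(weekly)
    if frame.empty:
        raise ValueError("no weekly CPUE rows")
    frame["month"] = frame["week_start"].dt.to_period("M")
    months = pd.period_range(frame["month"].min(), frame["month"].max(), freq="M")
    groups = list(dict.fromkeys(frame["group"]))

    rows = []
    for month in months:
        for group in groups:
            sel = frame[(frame["month"] == month) & (frame["group"] == group)]
            vals = sel["cpue"].dropna()
            if len(vals) == 0:
                mean, sd = np.nan, np.nan
            else:
                mean = float(vals.mean())
                if len(vals) == 1:
                    sd = 0.0 if single_week_sd == "zero" else np.nan
                else:
                    sd = float(vals.std(ddof=1))
            rows.append(
                {
                    "month": str(month),
                    "group": group,
                    "mean_cpue": mean,
                    "sd_cpue": sd,
                    "n_weeks": int(len(vals)),
                }
            )
    return pd.DataFrame(rows, columns=["month", "group", "mean_cpue", "sd_cpue", "n_weeks"])
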