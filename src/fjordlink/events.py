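"""Detection of contiguous anomaly runs against a percentile climatology.

A positive run (heat wave / high-salinity phase) is a maximal set of
consecutive days whose value exceeds the climatological upper envelope; a
negative run (cold spell / low-salinity phase) lies below the lower
envelope.  Runs of the same sign separated by at most ``max_gap``
non-qualifying, non-missing days may be merged; missing days always break
runs and never count toward gaps.  Runs at least ``min_duration`` days long
become events.

The default parameters follow the heat-wave definition of the Hobday-style
methodology: duration >= 5 days against the 90th percentile, no gap
joining (the underlying phases must be continuous); a ``max_gap=2`` mode is
available for sensitivity analysis.

Event intensity is summarised as day-degrees: the sum over event days of
the daily exceedance relative to a baseline curve.  Two baselines are
reported because the convention is ambiguous in field usage: the
climatological mean (the Hobday intensity convention, the default) and the
crossed percentile threshold (the envelope itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .climatology import ClimatologyTable
from .series_io import DailySeries

POSITIVE = 1
NEGATIVE = -1

_SIGN_LABEL = {POSITIVE: "positive", NEGATIVE: "negative"}


@dataclass(frozen=True)
class AnomalyEvent:
    """One contiguous exceedance run with duration and intensity metrics.

    ``day_degrees`` uses the climatological-mean baseline;
    ``day_degrees_threshold`` the crossed-envelope baseline.  Both are
    signed (positive events > 0, negative events < 0 under the threshold
    baseline).  ``max_exceedance`` is the signed peak daily exceedance
    beyond the crossed envelope.
    """

    variable: str
    sign: int
    start: pd.Timestamp
    end: pd.Timestamp
    duration: int
    day_degrees: float
    day_degrees_threshold: float
    max_exceedance: float

    @property
    def sign_label(self) -> str:
        return _SIGN_LABEL[self.sign]

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


def _daily_state(
    series: DailySeries, clim: ClimatologyTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-day exceedance state: +1 above upper, -1 below lower, 0 inside."""
    if clim.unit != "day_of_year":
        raise ValueError("daily event detection requires a day-of-year climatology")
    mean, lower, upper = clim.curves_for_dates(series.dates)
    v = series.values
    state = np.zeros(len(v), dtype=int)
    with np.errstate(invalid="ignore"):
        state[v > upper] = POSITIVE
        state[v < lower] = NEGATIVE
    missing = ~np.isfinite(v)
    state[missing] = 0
    return state, missing, lower, upper


def _qualifying_runs(state: np.ndarray, missing: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-sign runs as (sign, i0, i1) in chronological order."""
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(state)
    while i < n:
        s = state[i]
        if s == 0 or missing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == s and not missing[j + 1]:
            j += 1
        runs.append((s, i, j))
        i = j + 1
    return runs


def _merge_runs(
    runs: list[tuple[int, int, int]],
    state: np.ndarray,
    missing: np.ndarray,
    max_gap: int,
) -> list[tuple[int, int, int]]:
    if max_gap <= 0 or not runs:
        return runs
    merged = [runs[0]]
    for sign, i0, i1 in runs[1:]:
        psign, p0, p1 = merged[-1]
        gap = slice(p1 + 1, i0)
        gap_len = i0 - p1 - 1
        if (
            sign == psign
            and gap_len <= max_gap
            and not missing[gap].any()
            and (state[gap] == 0).all()
        ):
            merged[-1] = (psign, p0, i1)
        else:
            merged.append((sign, i0, i1))
    return merged


def detect_events(
    series: DailySeries,
    clim: ClimatologyTable,
    min_duration: int = 5,
    max_gap: int = 0,
) -> list[AnomalyEvent]:
    """Detect heat-wave/cold-spell style events in a daily series.

    Returns date-ordered, non-overlapping events of duration >=
    ``min_duration`` days.  With ``max_gap > 0``, same-sign runs separated
    by at most that many non-qualifying, non-missing days are merged before
    the duration filter (gap days then count toward the merged duration).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    state, missing, lower, upper = _daily_state(series, clim)
    runs = _merge_runs(_qualifying_runs(state, missing), state, missing, max_gap)

    events: list[AnomalyEvent] = []
    mean, _, _ = clim.curves_for_dates(series.dates)
    v = series.values
    for sign, i0, i1 in runs:
        duration = i1 - i0 + 1
        if duration < min_duration:
            continue
        window = slice(i0, i1 + 1)
        ok = np.isfinite(v[window])
        vals = v[window][ok]
        base_mean = mean[window][ok]
        threshold = (upper if sign == POSITIVE else lower)[window][ok]
        exceed = vals - threshold
        # gap days sit inside the envelope; clamp them to zero exceedance
        exceed = np.maximum(exceed, 0.0) if sign == POSITIVE else np.minimum(exceed, 0.0)
        events.append(
            AnomalyEvent(
                variable=series.variable,
                sign=int(sign),
                start=series.dates[i0],
                end=series.dates[i1],
                duration=int(duration),
                day_degrees=float((vals - base_mean).sum()),
                day_degrees_threshold=float(exceed.sum()),
                max_exceedance=float(exceed.max() if sign == POSITIVE else exceed.min()),
            )
        )
    return events


def event_day_degrees(
    series: DailySeries,
    clim: ClimatologyTable,
    event: AnomalyEvent,
    baseline: str = "mean",
) -> float:
    """Cumulative intensity (duration x intensity) of one event, signed.

    ``baseline="mean"`` sums value − climatological mean over event days
    (Hobday intensity convention); ``baseline="threshold"`` sums the
    exceedance beyond the crossed envelope, clamped to zero on any merged
    gap days that sit inside the envelope.
    """
    sel = (series.dates >= event.start) & (series.dates <= event.end)
    if not sel.any():
        raise ValueError("event window lies outside the series")
    mean, lower, upper = clim.curves_for_dates(series.dates)
    v = series.values[sel]
    ok = np.isfinite(v)
    if baseline == "mean":
        return float((v[ok] - mean[sel][ok]).sum())
    if baseline == "threshold":
        threshold = (upper if event.sign == POSITIVE else lower)[sel][ok]
        exceed = v[ok] - threshold
        exceed = (
            np.maximum(exceed, 0.0) if event.sign == POSITIVE else np.minimum(exceed, 0.0)
        )
        return float(exceed.sum())
    raise ValueError(f"unknown baseline {baseline!r}")


def net_daily_anomaly(
    series: DailySeries,
    clim: ClimatologyTable,
    events: Sequence[AnomalyEvent],
) -> DailySeries:
    """Signed daily exceedance beyond the crossed envelope on event days.

    Zero everywhere outside events; on event days, value − upper for
    positive events (when above) and value − lower for negative events
    (when below).  Summing this series over one event's days reproduces
    that event's threshold-baseline day-degrees.
    """
    _, lower, upper = clim.curves_for_dates(series.dates)
    out = np.zeros(len(series.dates))
    v = series.values
    for event in events:
        sel = (series.dates >= event.start) & (series.dates <= event.end)
        idx = np.flatnonzero(sel)
        for i in idx:
            if not np.isfinite(v[i]):
                continue
            if event.sign == POSITIVE:
                out[i] = max(v[i] - upper[i], 0.0)
            else:
                out[i] = min(v[i] - lower[i], 0.0)
    return DailySeries(
        variable=f"{series.variable}_net_anomaly",
        dates=series.dates,
        values=out,
        coverage=series.coverage.copy(),
    )


def events_frame(events: Iterable[AnomalyEvent]) -> pd.DataFrame:
    """Tabulate events for CSV export."""
    rows = [
        {
            "variable": e.variable,
            "sign": e.sign_label,
            "start": e.start.strftime("%Y-%m-%d"),
            "end": e.end.strftime("%Y-%m-%d"),
            "duration": e.duration,
            "day_degrees_mean_baseline": e.day_degrees,
            "day_degrees_threshold_baseline": e.day_degrees_threshold,
            "max_exceedance": e.max_exceedance,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "sign",
            "start",
            "end",
            "duration",
            "day_degrees_mean_baseline",
            "day_degrees_threshold_baseline",
            "max_exceedance",
        ],
    )
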