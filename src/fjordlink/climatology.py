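"""Long-term reference climatologies with percentile envelopes.

For every calendar unit (day-of-year for hydrographic variables,
week-of-cohort-year for weekly abundance) the climatology holds the
long-term mean and a lower/upper percentile envelope (10th/90th by
default), pooled across years inside a circular window around the unit.
Contiguous exceedances of the envelope are what the event detector calls
heat waves, cold spells and high-/low-salinity (or abundance) anomalies.

Calendar keying is leap-aware: dates are mapped onto a 366-day axis where
unit 60 is 29 February, so the same calendar day always lands on the same
unit regardless of year length and no day is deleted.  The envelope is
periodic (unit 366 wraps to unit 1).

The percentile estimator is sort-with-linear-interpolation between order
statistics (numpy's ``linear`` method); with the handful of years a coastal
observatory accumulates the estimator choice is material, so it is recorded
in the table's parameter metadata and switchable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DAYS_PER_CYCLE = 366
WEEKS_PER_CYCLE = 53


def leap_day_of_year(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to the 366-day leap-calendar axis (1..366, Feb 29 = 60)."""
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy(dtype=int)
    shift = (~dates.is_leap_year) & (doy >= 60)
    return doy + shift.astype(int)


@dataclass
class ClimatologyTable:
    """Per-calendar-unit long-term mean and percentile envelope.

    ``unit`` is either ``"day_of_year"`` (366 entries) or ``"week_of_year"``
    (53 entries, cohort-week keying).  ``n_years`` counts the distinct years
    contributing to each unit's pool; ``n_pool`` the pooled observations.
    All parameter choices are recorded in ``params``.
    """

    unit: str
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_years: np.ndarray
    n_pool: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mean", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_years = np.asarray(self.n_years, dtype=int)
        self.n_pool = np.asarray(self.n_pool, dtype=int)
        n = self.cycle_length
        for name in ("mean", "lower", "upper", "n_years", "n_pool"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries for unit {self.unit!r}")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower envelope exceeds upper envelope")

    @property
    def cycle_length(self) -> int:
        if self.unit == "day_of_year":
            return DAYS_PER_CYCLE
        if self.unit == "week_of_year":
            return WEEKS_PER_CYCLE
        raise ValueError(f"unknown climatology unit {self.unit!r}")

    def curves_at(self, units: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mean, lower, upper) evaluated at 1-based unit indices."""
        idx = np.asarray(units, dtype=int) - 1
        if np.any((idx < 0) | (idx >= self.cycle_length)):
            raise ValueError("unit index outside the calendar cycle")
        return self.mean[idx], self.lower[idx], self.upper[idx]

    def curves_for_dates(
        self, dates: pd.DatetimeIndex
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.unit != "day_of_year":
            raise ValueError("date lookup requires a day-of-year climatology")
        return self.curves_at(leap_day_of_year(dates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": np.arange(1, self.cycle_length + 1),
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
                "n_years": self.n_years,
                "n_pool": self.n_pool,
            }
        )

    def write(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON sidecar with the parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"unit": self.unit, **self.params}, indent=2))


def _circular_smooth(curve: np.ndarray, span: int) -> np.ndarray:
    """Circular moving average; preserves the curve's global mean exactly."""
    span = int(span)
    if span <= 1:
        return curve
    if span % 2 == 0:
        span += 1
    half = span // 2
    ext = np.concatenate([curve[-half:], curve, curve[:half]])
    return np.convolve(ext, np.ones(span) / span, mode="valid")


def _pooled_envelope(
    units: np.ndarray,
    years: np.ndarray,
    values: np.ndarray,
    cycle_length: int,
    window_halfwidth: int,
    percentile_pair: tuple[float, float],
    estimator: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    low_q, high_q = percentile_pair
    by_unit_values: list[np.ndarray] = []
    by_unit_years: list[np.ndarray] = []
    for u in range(1, cycle_length + 1):
        sel = units == u
        by_unit_values.append(values[sel])
        by_unit_years.append(years[sel])

    mean = np.empty(cycle_length)
    lower = np.empty(cycle_length)
    upper = np.empty(cycle_length)
    n_years = np.empty(cycle_length, dtype=int)
    n_pool = np.empty(cycle_length, dtype=int)
    offsets = np.arange(-window_halfwidth, window_halfwidth + 1)
    for u in range(cycle_length):
        members = (u + offsets) % cycle_length
        pool = np.concatenate([by_unit_values[m] for m in members])
        pool_years = np.concatenate([by_unit_years[m] for m in members])
        if pool.size == 0:
            raise ValueError(
                f"empty climatology pool for unit {u + 1} "
                f"(window halfwidth {window_halfwidth})"
            )
        mean[u] = pool.mean()
        lower[u] = np.quantile(pool, low_q, method=estimator)
        upper[u] = np.quantile(pool, high_q, method=estimator)
        n_years[u] = len(np.unique(pool_years))
        n_pool[u] = pool.size
    return mean, lower, upper, n_years, n_pool


def build_climatology(
    series,
    window_halfwidth: int = 5,
    smooth_span: int = 31,
    percentile_pair: tuple[float, float] = (0.1, 0.9),
    min_years: int = 2,
    estimator: str = "linear",
) -> ClimatologyTable:
    """Build a day-of-year climatology from a multi-year daily series.

    For each calendar day d, all non-missing values whose leap-aware
    day-of-year lies within ``±window_halfwidth`` of d (circularly, across
    all years) are pooled; the pool's mean and the configured percentile
    pair give the reference curves, which are then optionally smoothed with
    a circular moving average of ``smooth_span`` days.

    Raises if fewer than ``min_years`` distinct years contribute, or if any
    unit's pool is empty after windowing.
    """
    low_q, high_q = percentile_pair
    if not (0.0 < low_q < high_q < 1.0):
        raise ValueError("percentile_pair must satisfy 0 < low < high < 1")
    if window_halfwidth < 0:
        raise ValueError("window_halfwidth must be >= 0")

    finite = np.isfinite(series.values)
    if int(pd.DatetimeIndex(series.dates[finite]).year.nunique()) < min_years:
        raise ValueError(f"climatology requires data from >= {min_years} years")

    units = leap_day_of_year(series.dates)[finite]
    years = series.dates.year.to_numpy()[finite]
    values = series.values[finite]

    mean, lower, upper, n_years, n_pool = _pooled_envelope(
        units, years, values, DAYS_PER_CYCLE, window_halfwidth, percentile_pair, estimator
    )
    mean = _circular_smooth(mean, smooth_span)
    lower = _circular_smooth(lower, smooth_span)
    upper = _circular_smooth(upper, smooth_span)

    return ClimatologyTable(
        unit="day_of_year",
        mean=mean,
        lower=lower,
        upper=upper,
        n_years=n_years,
        n_pool=n_pool,
        params={
            "variable": series.variable,
            "window_halfwidth": window_halfwidth,
            "smooth_span": smooth_span,
            "percentile_pair": list(percentile_pair),
            "min_years": min_years,
            "estimator": estimator,
        },
    )


def build_weekly_climatology(
    week_units: Sequence[int],
    years: Sequence[int],
    values: Sequence[float],
    window_halfwidth: int = 1,
    smooth_span: int = 0,
    percentile_pair: tuple[float, float] = (0.1, 0.9),
    estimator: str = "linear",
    variable: str = "cpue",
) -> ClimatologyTable:
    """Build a week-of-year climatology from (week index, year, value) triples.

    Week indices are 1..53 on the cohort-anchored weekly grid; pooling uses
    ``window_halfwidth`` in weeks (default ±1 week).  Missing values are
    dropped before pooling.
    """
    low_q, high_q = percentile_pair
    if not (0.0 < low_q < high_q < 1.0):
        raise ValueError("percentile_pair must satisfy 0 < low < high < 1")
    units = np.asarray(week_units, dtype=int)
    yrs = np.asarray(years, dtype=int)
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    units, yrs, vals = units[finite], yrs[finite], vals[finite]
    if np.any((units < 1) | (units > WEEKS_PER_CYCLE)):
        raise ValueError("week indices must lie in 1..53")

    mean, lower, upper, n_years, n_pool = _pooled_envelope(
        units, yrs, vals, WEEKS_PER_CYCLE, window_halfwidth, percentile_pair, estimator
    )
    mean = _circular_smooth(mean, smooth_span)
    lower = _circular_smooth(lower, smooth_span)
    upper = _circular_smooth(upper, smooth_span)

    return ClimatologyTable(
        unit="week_of_year",
        mean=mean,
        lower=lower,
        upper=upper,
        n_years=n_years,
        n_pool=n_pool,
        params={
            "variable": variable,
            "window_halfwidth": window_halfwidth,
            "smooth_span": smooth_span,
            "percentile_pair": list(percentile_pair),
            "estimator": estimator,
        },
    )
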