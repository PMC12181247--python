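"""Shared fixtures: small synthetic series and hand-built climatologies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fjordlink.climatology import ClimatologyTable
from fjordlink.series_io import DailySeries

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_daily(
    values,
    start: str = "2015-01-01",
    variable: str = "temperature",
    coverage=None,
) -> DailySeries:
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    if coverage is None:
        coverage = np.where(np.isfinite(values), 1.0, 0.0)
    return DailySeries(variable=variable, dates=dates, values=values, coverage=coverage)


def flat_climatology(mean=0.0, lower=-1.0, upper=1.0, unit="day_of_year") -> ClimatologyTable:
    """A climatology with constant curves — handy for constructing exact cases."""
    n = 366 if unit == "day_of_year" else 53
    return ClimatologyTable(
        unit=unit,
        mean=np.full(n, float(mean)),
        lower=np.full(n, float(lower)),
        upper=np.full(n, float(upper)),
        n_years=np.full(n, 5),
        n_pool=np.full(n, 50),
        params={"constructed": True},
    )


@pytest.fixture
def flat_clim() -> ClimatologyTable:
    return flat_climatology()


@pytest.fixture
def constant_series() -> DailySeries:
    # spans two leap years so every calendar unit (incl. Feb 29) has data
    dates = pd.date_range("2012-01-01", "2016-12-31", freq="D")
    return DailySeries(
        variable="temperature",
        dates=dates,
        values=np.full(len(dates), 5.0),
        coverage=np.ones(len(dates)),
    )
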