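"""The polar biological year ("cohort year"): 01 August to 31 July.

Shallow-water biota at high latitudes peak in abundance during the polar
winter, so annual aggregation uses a year that starts in the polar summer:
cohort year Y spans 01 August of Y through 31 July of Y+1 (the 2014 cohort
year runs 2014-08-01 .. 2015-07-31).
"""

from __future__ import annotations

import pandas as pd

COHORT_START_MONTH = 8
COHORT_START_DAY = 1


def assign_cohort_year(date) -> int:
    """Cohort-year label Y such that 01 Aug Y <= date <= 31 Jul Y+1."""
    date = pd.Timestamp(date)
    return int(date.year if date.month >= COHORT_START_MONTH else date.year - 1)


def cohort_year_start(cohort_year: int) -> pd.Timestamp:
    return pd.Timestamp(year=int(cohort_year), month=COHORT_START_MONTH, day=COHORT_START_DAY)


def cohort_year_end(cohort_year: int) -> pd.Timestamp:
    """Last day of the cohort year (31 July of the following calendar year)."""
    return cohort_year_start(int(cohort_year) + 1) - pd.Timedelta(days=1)
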