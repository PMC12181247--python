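"""Reading, writing and daily aggregation of observatory time series.

Three kinds of tabular inputs are handled, all plain delimited text:

* raw high-frequency samples of one hydrographic variable
  (``timestamp, value`` — timestamps ISO 8601, interpreted as UTC);
* canonical daily-mean series (``date, value, coverage``);
* weekly stereoscopic survey tables
  (``week_start, image_pairs`` plus one column per biotic group).

Daily binning is by UTC calendar date.  Rows that cannot be parsed are
reported with their line numbers and the read continues; long observatory
records routinely contain glitches and silently dropping them hides data
problems from the analyst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fjordlink")

#: Controlled vocabulary of biotic groups (survey-table columns).
BIOTIC_GROUPS: tuple[str, ...] = (
    "appendicularia",
    "benthic_crustacea",
    "chaetognatha",
    "fish",
    "jellyfish",
    "pelagic_crustacea",
    "pteropoda",
    "others",
)

#: Synonyms that appear in survey exports; canonicalised on read.
GROUP_ALIASES: Mapping[str, str] = {
    "scyphozoa": "jellyfish",
    "pisces": "fish",
    "decapoda": "benthic_crustacea",
}

#: Label for the community-wide (all groups summed) abundance series.
TOTAL: str = "TOTAL"


def canonical_group(name: str) -> str:
    """Map a group label (or alias) to its canonical vocabulary entry.

    Raises ``ValueError`` for labels outside the controlled vocabulary.
    """
    key = name.strip().lower()
    key = GROUP_ALIASES.get(key, key)
    if key not in BIOTIC_GROUPS:
        raise ValueError(f"unknown biotic group label: {name!r}")
    return key


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """One raw measurement: UTC timestamp plus value (°C or PSU).

    ``value`` may be NaN for an explicitly missing measurement; such samples
    do not contribute to daily means or coverage.
    """

    timestamp: pd.Timestamp
    value: float


@dataclass(frozen=True)
class RejectedRow:
    """A raw-table row that could not be parsed, with provenance."""

    line: int  # 1-based line number in the file (header = line 1)
    reason: str
    raw: str


@dataclass
class ReadResult:
    """Samples in file order plus the rows that failed to parse."""

    samples: list[Sample]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class DailySeries:
    """Dated daily means of one variable with a missing-data mask.

    ``dates`` is a contiguous daily ``DatetimeIndex`` spanning first to last
    observed date; ``values`` holds daily means with NaN for missing days;
    ``coverage`` is the fraction of expected samples present per day in
    [0, 1].
    """

    variable: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if not (len(self.dates) == len(self.values) == len(self.coverage)):
            raise ValueError("dates, values and coverage must have equal length")
        if len(self.dates) and not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if self.dates.has_duplicates:
            raise ValueError("duplicate dates in DailySeries")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "value": self.values,
                "coverage": self.coverage,
            }
        )


@dataclass(frozen=True)
class SurveyRecord:
    """One week of stereoscopic survey effort and organism counts."""

    week_start: pd.Timestamp
    image_pairs: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.image_pairs < 0:
            raise ValueError("image_pairs must be non-negative")
        for group, count in self.counts.items():
            if group not in BIOTIC_GROUPS:
                raise ValueError(f"unknown biotic group label: {group!r}")
            if count < 0:
                raise ValueError(f"negative count for group {group!r}")


# ---------------------------------------------------------------------------
# raw sample tables
# ---------------------------------------------------------------------------

def read_series(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> ReadResult:
    """Read raw (timestamp, value) samples from a delimited text file.

    ``schema`` maps the logical column roles ``timestamp`` and ``value`` to
    the column names used in the file (defaults to those literal names).
    Rows whose timestamp cannot be parsed are collected as rejects and
    logged; a parseable timestamp with an unparseable or empty value yields
    a Sample with NaN value (explicitly missing measurement).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    ts_col = schema.get("timestamp", "timestamp")
    val_col = schema.get("value", "value")

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in (ts_col, val_col):
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} not found in {path}")

    timestamps = pd.to_datetime(raw[ts_col], errors="coerce", utc=True, format="mixed")
    values = pd.to_numeric(raw[val_col].where(raw[val_col] != ""), errors="coerce")

    samples: list[Sample] = []
    rejects: list[RejectedRow] = []
    for i in range(len(raw)):
        ts = timestamps.iloc[i]
        if pd.isna(ts):
            rejects.append(
                RejectedRow(
                    line=i + 2,  # +1 header, +1 one-based
                    reason=f"unparseable timestamp {raw[ts_col].iloc[i]!r}",
                    raw=delimiter.join(str(v) for v in raw.iloc[i].tolist()),
                )
            )
            continue
        v = values.iloc[i]
        if not np.isfinite(v):
            v = np.nan
        samples.append(Sample(timestamp=ts.tz_localize(None), value=float(v)))

    for reject in rejects:
        logger.warning("%s line %d rejected: %s", path.name, reject.line, reject.reason)
    if not samples:
        raise ValueError(f"zero parseable rows in {path}")
    return ReadResult(samples=samples, rejects=rejects)


def write_series(samples: Iterable[Sample], path: str | Path) -> None:
    """Write raw samples back to CSV (timestamp ISO 8601, value)."""
    rows = [(s.timestamp.isoformat(), s.value) for s in samples]
    pd.DataFrame(rows, columns=["timestamp", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# daily aggregation
# ---------------------------------------------------------------------------

def aggregate_daily(
    samples: Sequence[Sample],
    min_coverage: float = 0.5,
    expected_per_day: int | None = None,
    variable: str = "value",
) -> DailySeries:
    """Aggregate raw samples to daily means on the UTC calendar-date grid.

    One entry is produced per calendar date spanning the first to the last
    sample date; dates with no samples are present with missing value.  The
    daily value is the arithmetic mean of that date's finite samples and is
    marked missing when coverage (finite samples present / expected samples
    per day) falls below ``min_coverage``.

    ``expected_per_day`` defaults to an estimate from the median inter-sample
    interval, so a nominally hourly record expects 24 samples per day.
    """
    if not samples:
        raise ValueError("aggregate_daily requires at least one sample")
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError("min_coverage must lie in [0, 1]")

    ts = pd.DatetimeIndex([s.timestamp for s in samples])
    vals = np.array([s.value for s in samples], dtype=float)

    if expected_per_day is None:
        uniq = np.unique(ts.view("int64"))
        if len(uniq) > 1:
            dt = float(np.median(np.diff(uniq))) / 1e9  # seconds
            expected_per_day = max(1, int(round(86400.0 / dt))) if dt > 0 else 1
        else:
            expected_per_day = 1

    frame = pd.DataFrame({"date": ts.floor("D"), "value": vals})
    finite = frame.dropna(subset=["value"])
    grouped = finite.groupby("date")["value"]
    means = grouped.mean()
    counts = grouped.size()

    dates = pd.date_range(frame["date"].min(), frame["date"].max(), freq="D")
    values = means.reindex(dates).to_numpy(dtype=float)
    coverage = np.minimum(
        counts.reindex(dates, fill_value=0).to_numpy(dtype=float) / expected_per_day,
        1.0,
    )
    values[coverage < min_coverage] = np.nan
    return DailySeries(variable=variable, dates=dates, values=values, coverage=coverage)


def write_daily(series: DailySeries, path: str | Path) -> None:
    """Write a daily series as canonical CSV (date, value, coverage)."""
    series.to_frame().to_csv(path, index=False)


def read_daily(path: str | Path, variable: str = "value") -> DailySeries:
    """Read a canonical daily-series CSV back into a :class:`DailySeries`."""
    frame = pd.read_csv(path)
    for col in ("date", "value", "coverage"):
        if col not in frame.columns:
            raise ValueError(f"daily-series CSV {path} lacks column {col!r}")
    return DailySeries(
        variable=variable,
        dates=pd.DatetimeIndex(pd.to_datetime(frame["date"])),
        values=frame["value"].to_numpy(dtype=float),
        coverage=frame["coverage"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# weekly survey tables
# ---------------------------------------------------------------------------

def read_survey(path: str | Path) -> list[SurveyRecord]:
    """Read a weekly survey CSV (week_start, image_pairs, one column/group).

    Group column names may use the alias vocabulary (scyphozoa → jellyfish,
    pisces → fish, decapoda → benthic_crustacea); unknown columns raise.
    Empty count cells are treated as zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    for col in ("week_start", "image_pairs"):
        if col not in frame.columns:
            raise ValueError(f"survey CSV {path} lacks column {col!r}")
    group_cols = [c for c in frame.columns if c not in ("week_start", "image_pairs")]
    canonical = {col: canonical_group(col) for col in group_cols}

    records: list[SurveyRecord] = []
    for _, row in frame.iterrows():
        counts: dict[str, int] = {g: 0 for g in BIOTIC_GROUPS}
        for col, group in canonical.items():
            val = row[col]
            count = 0 if pd.isna(val) else int(val)
            if count < 0:
                raise ValueError(f"negative count in column {col!r}")
            counts[group] += count
        records.append(
            SurveyRecord(
                week_start=pd.Timestamp(row["week_start"]),
                image_pairs=int(row["image_pairs"]),
                counts=counts,
            )
        )
    return records


def write_survey(records: Iterable[SurveyRecord], path: str | Path) -> None:
    """Write survey records as CSV with one column per canonical group."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "week_start": rec.week_start.strftime("%Y-%m-%d"),
            "image_pairs": rec.image_pairs,
        }
        for group in BIOTIC_GROUPS:
            row[group] = int(rec.counts.get(group, 0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
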