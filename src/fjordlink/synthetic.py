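"""Synthetic observatory datasets with known ground truth.

The generator emulates the structure of a polar-fjord shallow-water
observatory record: seasonal sinusoidal temperature (summer-warm) and
salinity (winter-high) cycles with AR(1) daily noise and injected
warm/cold or high-/low-salinity boxcar events of known timing and
amplitude; and weekly survey counts with winter-peaked seasonal profiles,
gamma-mixed (negative-binomial) overdispersion, multi-group composition,
random effort dropout, and a configurable coupling of expected abundance
to the cohort-level temperature anomaly exposure.

The coupling acts on cohort-level net day-degrees rather than on the
instantaneous temperature: cumulative exposure within a cohort year, not a
momentary value, is what plausibly drives the community response, and it
is exactly the quantity the downstream rank statistics test for.

Sinusoids are evaluated on the same leap-aware 366-day axis the
climatology uses, so with zero noise every year contributes an identical
value per calendar unit and a series' own climatology collapses onto it.

A single master seed is split into named substreams (one per variable and
biotic group), so adding a group leaves all other streams untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .biotic import NOMINAL_EFFORT
from .climatology import leap_day_of_year
from .cohort_calendar import assign_cohort_year, cohort_year_end, cohort_year_start
from .series_io import BIOTIC_GROUPS, DailySeries, SurveyRecord

DAYS_PER_CYCLE = 366.0


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic, name-keyed child RNG of the master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectedEvent:
    """A boxcar anomaly added to one abiotic variable."""

    variable: str  # "temperature" | "salinity"
    sign: int  # +1 warm/salty, -1 cold/fresh
    start: pd.Timestamp
    duration: int  # days
    amplitude: float  # variable units, > 0

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.start) + pd.Timedelta(days=self.duration - 1)


@dataclass(frozen=True)
class GroupSpec:
    """Seasonal abundance profile of one biotic group.

    Expected CPUE at nominal effort peaks at ``peak_cpue`` in cohort week
    ``peak_week`` (week 1 = the week of 01 August; polar-winter peaks sit
    around weeks 18–31, i.e. December–February) and decays as a raised
    cosine to ``floor_fraction`` of the peak.
    """

    name: str
    peak_week: int
    peak_cpue: float
    sharpness: float = 2.0
    floor_fraction: float = 0.02


#: Winter-peaked community with abundances loosely proportional to the
#: relative frequencies of the eight groups in shallow polar fjord surveys.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("appendicularia", peak_week=22, peak_cpue=8.0),
    GroupSpec("benthic_crustacea", peak_week=26, peak_cpue=18.0),
    GroupSpec("chaetognatha", peak_week=20, peak_cpue=6.0),
    GroupSpec("fish", peak_week=24, peak_cpue=14.0),
    GroupSpec("jellyfish", peak_week=18, peak_cpue=10.0),
    GroupSpec("pelagic_crustacea", peak_week=28, peak_cpue=15.0),
    GroupSpec("pteropoda", peak_week=21, peak_cpue=7.0),
    GroupSpec("others", peak_week=25, peak_cpue=1.5),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic observatory scenario.

    Temperature/salinity units are °C and PSU; phases are leap-calendar
    days-of-year of the seasonal maximum.  ``dispersion`` is the
    negative-binomial shape k (variance = mu + mu²/k), ``coupling_beta``
    the effect of standardized cohort temperature net day-degrees on log
    expected CPUE.
    """

    start: pd.Timestamp = pd.Timestamp("2012-08-01")
    end: pd.Timestamp = pd.Timestamp("2020-07-31")
    temp_mean_annual: float = 3.0
    temp_seasonal_amplitude: float = 3.5
    temp_phase: int = 220  # maximum in early August
    sal_mean: float = 34.0
    sal_amplitude: float = 0.8
    sal_phase: int = 50  # maximum in late winter
    ar1_coefficient: float = 0.7
    temp_noise_sd: float = 0.35
    sal_noise_sd: float = 0.15
    injected_events: tuple[InjectedEvent, ...] = ()
    biota_groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    dispersion: float = 5.0
    coupling_beta: float = 0.0
    effort_dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for amp in (self.temp_seasonal_amplitude, self.sal_amplitude):
            if amp < 0:
                raise ValueError("seasonal amplitudes must be >= 0")
        _check_injection_overlap(self.injected_events)

    def cohorts(self) -> list[int]:
        """Cohort years fully contained in [start, end]."""
        first = assign_cohort_year(self.start)
        if cohort_year_start(first) < self.start:
            first += 1
        out = []
        c = first
        while cohort_year_end(c) <= self.end:
            out.append(c)
            c += 1
        return out


def _check_injection_overlap(events: Sequence[InjectedEvent]) -> None:
    by_var: dict[str, list[InjectedEvent]] = {}
    for ev in events:
        by_var.setdefault(ev.variable, []).append(ev)
    for var, evs in by_var.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping injected {var} events at {a.start.date()} / {b.start.date()}"
                )


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    injected_events: list[InjectedEvent]
    cohort_net_day_degrees: dict[int, float]  # temperature, amplitude x days
    expected_cpue: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticDataset:
    temperature: DailySeries
    salinity: DailySeries
    survey: list[SurveyRecord]
    truth: GroundTruth
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# abiotic generation
# ---------------------------------------------------------------------------

def _seasonal(dates: pd.DatetimeIndex, mean: float, amplitude: float, phase: int) -> np.ndarray:
    units = leap_day_of_year(dates).astype(float)
    return mean + amplitude * np.cos(2.0 * np.pi * (units - phase) / DAYS_PER_CYCLE)


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    burn = 100
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, n + burn)
    return lfilter([1.0], [1.0, -phi], eps)[burn:]


def generate_abiotic(config: ScenarioConfig) -> tuple[DailySeries, DailySeries, GroundTruth]:
    """Daily temperature and salinity series plus injection ground truth.

    value(d) = seasonal sinusoid + AR(1) noise + Σ injected boxcars.
    Identical seed implies identical output; with zero noise the series is
    exactly sinusoid + injections.
    """
    dates = pd.date_range(config.start, config.end, freq="D")
    n = len(dates)

    specs = {
        "temperature": (config.temp_mean_annual, config.temp_seasonal_amplitude,
                        config.temp_phase, config.temp_noise_sd),
        "salinity": (config.sal_mean, config.sal_amplitude,
                     config.sal_phase, config.sal_noise_sd),
    }
    series: dict[str, DailySeries] = {}
    for var, (mean, amp, phase, noise_sd) in specs.items():
        values = _seasonal(dates, mean, amp, phase)
        values = values + _ar1_noise(
            substream(config.seed, f"abiotic:{var}"), n, config.ar1_coefficient, noise_sd
        )
        for ev in config.injected_events:
            if ev.variable != var:
                continue
            sel = (dates >= ev.start) & (dates <= ev.end)
            values[sel] += ev.sign * ev.amplitude
        series[var] = DailySeries(
            variable=var, dates=dates, values=values, coverage=np.ones(n)
        )

    net: dict[int, float] = {c: 0.0 for c in config.cohorts()}
    for ev in config.injected_events:
        if ev.variable != "temperature":
            continue
        for d in pd.date_range(ev.start, ev.end, freq="D"):
            c = assign_cohort_year(d)
            if c in net:
                net[c] += ev.sign * ev.amplitude
    truth = GroundTruth(
        injected_events=list(config.injected_events), cohort_net_day_degrees=net
    )
    return series["temperature"], series["salinity"], truth


# ---------------------------------------------------------------------------
# biotic generation
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _seasonal_cpue(spec: GroupSpec, week: np.ndarray) -> np.ndarray:
    shape = ((1.0 + np.cos(2.0 * np.pi * (week - spec.peak_week) / 52.0)) / 2.0) ** spec.sharpness
    return spec.peak_cpue * (spec.floor_fraction + (1.0 - spec.floor_fraction) * shape)


def generate_biota(config: ScenarioConfig, truth: GroundTruth) -> list[SurveyRecord]:
    """Weekly survey records coupled to the abiotic ground truth.

    Expected CPUE per group/week = seasonal profile x
    exp(coupling_beta x standardized cohort net day-degrees); observed
    counts are gamma-mixed Poisson (negative binomial, shape =
    ``dispersion``) at the week's actual effort.  Effort is 336 image
    pairs, reduced to a uniform draw in [24, 335] with probability
    ``effort_dropout`` (weeks that land below the effort floor become
    missing downstream).  Also fills ``truth.expected_cpue``.
    """
    cohorts = config.cohorts()
    if not cohorts:
        raise ValueError("scenario span contains no complete cohort year")
    z_by_cohort = dict(
        zip(
            cohorts,
            _standardize(
                np.array([truth.cohort_net_day_degrees.get(c, 0.0) for c in cohorts])
            ),
        )
    )

    week_starts: list[pd.Timestamp] = []
    week_index: list[int] = []
    week_z: list[float] = []
    for c in cohorts:
        anchor = cohort_year_start(c)
        for k in range(52):  # the 1-2 day remainder week is not surveyed
            week_starts.append(anchor + pd.Timedelta(days=7 * k))
            week_index.append(k + 1)
            week_z.append(z_by_cohort[c])
    weeks = np.asarray(week_index, dtype=float)
    z = np.asarray(week_z)
    n_weeks = len(weeks)

    effort_rng = substream(config.seed, "effort")
    effort = np.full(n_weeks, NOMINAL_EFFORT, dtype=int)
    dropped = effort_rng.random(n_weeks) < config.effort_dropout
    effort[dropped] = effort_rng.integers(24, NOMINAL_EFFORT, size=int(dropped.sum()))

    counts: dict[str, np.ndarray] = {}
    expected_rows = []
    k_disp = config.dispersion
    for spec in config.biota_groups:
        mu = _seasonal_cpue(spec, weeks) * np.exp(config.coupling_beta * z)
        mu_effort = mu * effort / NOMINAL_EFFORT
        rng = substream(config.seed, f"biota:{spec.name}")
        lam = np.where(
            mu_effort > 0, rng.gamma(k_disp, np.maximum(mu_effort, 1e-300) / k_disp), 0.0
        )
        counts[spec.name] = rng.poisson(lam)
        expected_rows.append(
            pd.DataFrame(
                {"week_start": week_starts, "group": spec.name, "expected_cpue": mu}
            )
        )
    truth.expected_cpue = pd.concat(expected_rows, ignore_index=True)

    records = []
    for i, ws in enumerate(week_starts):
        records.append(
            SurveyRecord(
                week_start=ws,
                image_pairs=int(effort[i]),
                counts={g: int(counts[g][i]) for g in counts},
            )
        )
    return records


def generate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Generate the complete dataset (abiotic series, survey, truth)."""
    temperature, salinity, truth = generate_abiotic(config)
    survey = generate_biota(config, truth)
    return SyntheticDataset(
        temperature=temperature,
        salinity=salinity,
        survey=survey,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def demo_scenario(
    seed: int = 0,
    coupling_beta: float = 0.0,
    n_years: int = 8,
    start: str | pd.Timestamp = "2012-08-01",
    events_per_year: float = 2.5,
    regime_strength: float = 1.5,
    **overrides,
) -> ScenarioConfig:
    """An 8-cohort-year scenario with randomized injected events.

    Each cohort year receives a Poisson number of temperature events
    (5–20 days, 1–3 °C) whose sign is biased by a per-year regime draw —
    mimicking alternation between warm-saline Atlantic-inflow phases rich
    in heat waves and cold-fresh Arctic phases dominated by cold spells —
    plus independent salinity events (0.3–1.2 PSU).  The regime bias makes
    cohort net day-degrees vary strongly between years, which is the
    contrast the coupling statistics need.
    """
    start = pd.Timestamp(start)
    end = cohort_year_end(assign_cohort_year(start) + n_years - 1)
    rng = substream(seed, "scenario")
    injected: list[InjectedEvent] = []
    for c in range(assign_cohort_year(start), assign_cohort_year(start) + n_years):
        anchor = cohort_year_start(c)
        regime = rng.normal()
        for var, rate, amp_range in (
            ("temperature", events_per_year, (1.0, 3.0)),
            ("salinity", events_per_year * 0.8, (0.3, 1.2)),
        ):
            n_ev = int(rng.poisson(rate))
            for _ in range(n_ev):
                if var == "temperature":
                    p_warm = 1.0 / (1.0 + np.exp(-regime_strength * regime))
                    sign = 1 if rng.random() < p_warm else -1
                else:
                    sign = 1 if rng.random() < 0.5 else -1
                duration = int(rng.integers(5, 21))
                amplitude = float(rng.uniform(*amp_range))
                for _attempt in range(50):
                    offset = int(rng.integers(0, 365 - duration))
                    cand = InjectedEvent(
                        variable=var,
                        sign=sign,
                        start=anchor + pd.Timedelta(days=offset),
                        duration=duration,
                        amplitude=amplitude,
                    )
                    try:
                        _check_injection_overlap(
                            [e for e in injected if e.variable == var] + [cand]
                        )
                    except ValueError:
                        continue
                    injected.append(cand)
                    break
    return ScenarioConfig(
        start=start,
        end=end,
        injected_events=tuple(injected),
        coupling_beta=coupling_beta,
        seed=seed,
        **overrides,
    )


def run_coupling_experiment(
    seed: int,
    coupling_beta: float = 0.0,
    **scenario_overrides,
):
    """Full pipeline on one demo scenario: generate → detect → cohort → rank-OLS.

    Returns the rank-regression result coupling the TOTAL biotic cohort
    anomaly sums to the temperature cohort day-degree sums.
    """
    from .climatology import build_climatology
    from .cohort_stats import cohort_cumulative, coupling_analysis
    from .events import detect_events

    cfg = demo_scenario(seed=seed, coupling_beta=coupling_beta, **scenario_overrides)
    dataset = generate_scenario(cfg)
    clim = build_climatology(dataset.temperature)
    evs = detect_events(dataset.temperature, clim)
    summaries = cohort_cumulative(evs, dataset.temperature, clim)
    return coupling_analysis(summaries, dataset.survey)


def event_day_jaccard(injected: Sequence[InjectedEvent], detected, variable: str) -> float:
    """Jaccard overlap between injected and detected (day, sign) sets."""
    truth: set[tuple[pd.Timestamp, int]] = set()
    for ev in injected:
        if ev.variable != variable:
            continue
        for d in pd.date_range(ev.start, ev.end, freq="D"):
            truth.add((d, ev.sign))
    found: set[tuple[pd.Timestamp, int]] = set()
    for ev in detected:
        for d in pd.date_range(ev.start, ev.end, freq="D"):
            found.add((d, ev.sign))
    if not truth and not found:
        return 1.0
    return len(truth & found) / len(truth | found)


def zero_noise_scenario(
    seed: int = 0,
    injections: Sequence[InjectedEvent] | None = None,
) -> ScenarioConfig:
    """A noise-free multi-year scenario with well-separated injections.

    Injections are placed in distinct seasons so no two events of one
    variable share a day-of-year window; against a climatology built with
    ``window_halfwidth=0`` and no smoothing, every injected day then
    exceeds the envelope exactly and no clean day does.
    """
    if injections is None:
        injections = (
            InjectedEvent("temperature", +1, pd.Timestamp("2014-10-10"), 10, 3.0),
            InjectedEvent("temperature", -1, pd.Timestamp("2016-02-05"), 12, 2.0),
            InjectedEvent("temperature", +1, pd.Timestamp("2018-05-20"), 8, 1.5),
            InjectedEvent("salinity", -1, pd.Timestamp("2015-07-01"), 9, 1.0),
        )
    return ScenarioConfig(
        temp_noise_sd=0.0,
        sal_noise_sd=0.0,
        effort_dropout=0.0,
        injected_events=tuple(injections),
        seed=seed,
    )
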