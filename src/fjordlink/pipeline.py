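"""One-command pipeline: generation/ingest → climatology → events → biotic → stats.

Stages communicate through CSV tables in the run directory, so each stage
can be re-run independently (the CLI subcommands map one-to-one onto
stages).  A JSON manifest records the package version, the fully resolved
parameters, the seed and SHA-256 digests of all inputs and outputs;
re-running an identical configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__, biotic, climatology, cohort_stats, events, series_io, synthetic
from .series_io import BIOTIC_GROUPS, TOTAL

logger = logging.getLogger("fjordlink")

ALL_STAGES: tuple[str, ...] = ("generate", "detect", "biotic", "cohort", "stats")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``scenario`` (synthetic generation) or the three input paths
    must be provided, not both.  Input series CSVs may be raw samples
    (``inputs_are_raw=True``, parsed through the schema block) or canonical
    daily tables.
    """

    # inputs
    scenario: synthetic.ScenarioConfig | None = None
    temperature_csv: str | None = None
    salinity_csv: str | None = None
    survey_csv: str | None = None
    inputs_are_raw: bool = False
    schema: dict = field(default_factory=lambda: {"timestamp": "timestamp", "value": "value"})
    min_coverage: float = 0.5
    # climatology
    window_halfwidth: int = 5
    smooth_span: int = 31
    percentile_low: float = 0.1
    percentile_high: float = 0.9
    # events
    min_duration: int = 5
    max_gap: int = 0
    baseline: str = "mean"
    # biotic
    window_halfwidth_weeks: int = 1
    effort_floor: int = 48
    min_duration_weeks: int = 1
    # statistics
    ranking_key: str = "net_sum"
    # run
    outdir: str = "fjordlink_run"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = any([self.temperature_csv, self.salinity_csv, self.survey_csv])
        if self.scenario is not None and has_paths:
            raise ValueError("provide either a scenario or input paths, not both")
        if self.scenario is None and not has_paths:
            raise ValueError("a scenario or input paths must be provided")
        if not 0.0 < self.percentile_low < self.percentile_high < 1.0:
            raise ValueError("percentile bounds must satisfy 0 < low < high < 1")

    @property
    def percentile_pair(self) -> tuple[float, float]:
        return (self.percentile_low, self.percentile_high)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            injected = tuple(
                synthetic.InjectedEvent(
                    variable=e["variable"],
                    sign=int(e["sign"]),
                    start=pd.Timestamp(e["start"]),
                    duration=int(e["duration"]),
                    amplitude=float(e["amplitude"]),
                )
                for e in scenario.pop("injected_events", [])
            )
            groups = scenario.pop("biota_groups", None)
            if groups is not None:
                groups = tuple(synthetic.GroupSpec(**g) for g in groups)
            else:
                groups = synthetic.DEFAULT_GROUPS
            scenario = synthetic.ScenarioConfig(
                injected_events=injected, biota_groups=groups, **scenario
            )
        raw.update(overrides)
        return cls(scenario=scenario, **raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        if self.scenario is not None:
            sc = dataclasses.asdict(self.scenario)
            sc["start"] = str(self.scenario.start.date())
            sc["end"] = str(self.scenario.end.date())
            sc["injected_events"] = [
                {
                    "variable": e.variable,
                    "sign": e.sign,
                    "start": str(pd.Timestamp(e.start).date()),
                    "duration": e.duration,
                    "amplitude": e.amplitude,
                }
                for e in self.scenario.injected_events
            ]
            out["scenario"] = sc
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class _Store:
    """In-memory stage handoff, backed by the run directory."""

    config: RunConfig
    outdir: Path
    temperature: series_io.DailySeries | None = None
    salinity: series_io.DailySeries | None = None
    survey: list | None = None
    clim: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    weekly: list | None = None
    abiotic_summaries: dict = field(default_factory=dict)

    def daily(self, variable: str) -> series_io.DailySeries:
        cached = getattr(self, variable)
        if cached is not None:
            return cached
        path = self.outdir / f"{variable}_daily.csv"
        if path.exists():
            series = series_io.read_daily(path, variable=variable)
        else:
            cfg_path = getattr(self.config, f"{variable}_csv")
            if cfg_path is None:
                raise FileNotFoundError(
                    f"no {variable} input: run the generate stage or set {variable}_csv"
                )
            if self.config.inputs_are_raw:
                result = series_io.read_series(cfg_path, schema=self.config.schema)
                series = series_io.aggregate_daily(
                    result.samples, min_coverage=self.config.min_coverage, variable=variable
                )
            else:
                series = series_io.read_daily(cfg_path, variable=variable)
        setattr(self, variable, series)
        return series

    def survey_records(self) -> list:
        if self.survey is not None:
            return self.survey
        path = self.outdir / "survey.csv"
        if not path.exists():
            if self.config.survey_csv is None:
                raise FileNotFoundError("no survey input: generate or set survey_csv")
            path = Path(self.config.survey_csv)
        self.survey = series_io.read_survey(path)
        return self.survey

    def weekly_cpue(self) -> list:
        if self.weekly is None:
            self.weekly = biotic.compute_weekly_cpue(
                self.survey_records(), effort_floor=self.config.effort_floor
            )
        return self.weekly


def _stage_generate(store: _Store) -> None:
    cfg = store.config
    if cfg.scenario is None:
        # file inputs: copy nothing, later stages read from the configured paths
        return
    scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
    dataset = synthetic.generate_scenario(scenario)
    store.temperature, store.salinity = dataset.temperature, dataset.salinity
    store.survey = dataset.survey
    series_io.write_daily(dataset.temperature, store.outdir / "temperature_daily.csv")
    series_io.write_daily(dataset.salinity, store.outdir / "salinity_daily.csv")
    series_io.write_survey(dataset.survey, store.outdir / "survey.csv")
    pd.DataFrame(
        [
            {
                "variable": e.variable,
                "sign": e.sign,
                "start": str(pd.Timestamp(e.start).date()),
                "duration": e.duration,
                "amplitude": e.amplitude,
            }
            for e in dataset.truth.injected_events
        ]
    ).to_csv(store.outdir / "truth_injected_events.csv", index=False)
    pd.DataFrame(
        sorted(dataset.truth.cohort_net_day_degrees.items()),
        columns=["cohort_year", "net_day_degrees"],
    ).to_csv(store.outdir / "truth_cohort_day_degrees.csv", index=False)
    dataset.truth.expected_cpue.to_csv(store.outdir / "truth_expected_cpue.csv", index=False)


def _stage_detect(store: _Store) -> None:
    cfg = store.config
    for variable in ("temperature", "salinity"):
        series = store.daily(variable)
        clim = climatology.build_climatology(
            series,
            window_halfwidth=cfg.window_halfwidth,
            smooth_span=cfg.smooth_span,
            percentile_pair=cfg.percentile_pair,
        )
        clim.write(store.outdir / f"climatology_{variable}.csv")
        evs = events.detect_events(
            series, clim, min_duration=cfg.min_duration, max_gap=cfg.max_gap
        )
        store.clim[variable] = clim
        store.events[variable] = evs
        net = events.net_daily_anomaly(series, clim, evs)
        series_io.write_daily(net, store.outdir / f"net_anomaly_{variable}.csv")
    frame = pd.concat(
        [events.events_frame(store.events[v]) for v in ("temperature", "salinity")],
        ignore_index=True,
    )
    frame.to_csv(store.outdir / "events.csv", index=False)


def _require_detect(store: _Store) -> None:
    if store.events:
        return
    path = store.outdir / "events.csv"
    if not path.exists():
        raise FileNotFoundError("events.csv not found: run the detect stage first")
    frame = pd.read_csv(path)
    for variable in ("temperature", "salinity"):
        series = store.daily(variable)
        clim = store.clim.get(variable)
        if clim is None:
            cfg = store.config
            clim = climatology.build_climatology(
                series,
                window_halfwidth=cfg.window_halfwidth,
                smooth_span=cfg.smooth_span,
                percentile_pair=cfg.percentile_pair,
            )
            store.clim[variable] = clim
        sub = frame[frame["variable"] == variable]
        store.events[variable] = [
            events.AnomalyEvent(
                variable=variable,
                sign=1 if row["sign"] == "positive" else -1,
                start=pd.Timestamp(row["start"]),
                end=pd.Timestamp(row["end"]),
                duration=int(row["duration"]),
                day_degrees=float(row["day_degrees_mean_baseline"]),
                day_degrees_threshold=float(row["day_degrees_threshold_baseline"]),
                max_exceedance=float(row["max_exceedance"]),
            )
            for _, row in sub.iterrows()
        ]


def _stage_biotic(store: _Store) -> None:
    cfg = store.config
    weekly = store.weekly_cpue()
    biotic.cpue_frame(weekly).assign(
        week_start=lambda f: f["week_start"].dt.strftime("%Y-%m-%d")
    ).to_csv(store.outdir / "weekly_cpue.csv", index=False)

    anomalies = []
    for group in (TOTAL, *BIOTIC_GROUPS):
        clim = biotic.build_group_climatology(
            weekly,
            group,
            window_halfwidth=cfg.window_halfwidth_weeks,
            percentile_pair=cfg.percentile_pair,
        )
        if group == TOTAL:
            clim.write(store.outdir / "climatology_cpue_total.csv")
        anomalies.extend(
            biotic.detect_biotic_anomalies(
                weekly, clim, group, min_duration_weeks=cfg.min_duration_weeks
            )
        )
    biotic.anomalies_frame(anomalies).to_csv(
        store.outdir / "biotic_anomalies.csv", index=False
    )
    biotic.monthly_summary(weekly).to_csv(store.outdir / "monthly_summary.csv", index=False)


def _stage_cohort(store: _Store) -> None:
    cfg = store.config
    _require_detect(store)
    summaries = []
    for variable in ("temperature", "salinity"):
        subs = cohort_stats.cohort_cumulative(
            store.events[variable],
            store.daily(variable),
            store.clim[variable],
            baseline=cfg.baseline,
        )
        store.abiotic_summaries[variable] = subs
        summaries.extend(subs)
    weekly = store.weekly_cpue()
    for group in (TOTAL, *BIOTIC_GROUPS):
        clim = biotic.build_group_climatology(
            weekly,
            group,
            window_halfwidth=cfg.window_halfwidth_weeks,
            percentile_pair=cfg.percentile_pair,
        )
        summaries.extend(
            cohort_stats.biotic_cohort_cumulative(
                weekly,
                clim,
                group,
                min_duration_weeks=cfg.min_duration_weeks,
                cohorts=[s.cohort_year for s in store.abiotic_summaries["temperature"]],
            )
        )
    cohort_stats.summaries_frame(summaries).to_csv(
        store.outdir / "cohort_summaries.csv", index=False
    )


def _stage_stats(store: _Store) -> None:
    cfg = store.config
    _require_detect(store)
    if not store.abiotic_summaries:
        _stage_cohort(store)

    # Mann–Kendall trend tests on per-cohort frequency and intensity series
    trend_rows = []
    for variable in ("temperature", "salinity"):
        subs = store.abiotic_summaries[variable]
        cohorts = [s.cohort_year for s in subs]
        table = cohort_stats.cohort_event_stats(
            store.events[variable], cohorts, baseline=cfg.baseline
        )
        for column in table.columns:
            series = table[column].to_numpy(dtype=float)
            try:
                res = cohort_stats.mann_kendall(series)
            except ValueError:
                continue
            trend_rows.append(
                {
                    "variable": variable,
                    "series": column,
                    "n": res.n,
                    "s_statistic": res.s_statistic,
                    "tau": res.tau,
                    "p_value": res.p_value,
                }
            )
    pd.DataFrame(trend_rows).to_csv(store.outdir / "trend_tests.csv", index=False)

    table = cohort_stats.group_coupling_table(
        store.abiotic_summaries["temperature"],
        store.survey_records(),
        ranking_key=cfg.ranking_key,
        min_duration_weeks=cfg.min_duration_weeks,
        window_halfwidth_weeks=cfg.window_halfwidth_weeks,
        percentile_pair=cfg.percentile_pair,
        effort_floor=cfg.effort_floor,
    )
    table.to_csv(store.outdir / "rank_regressions.csv", index=False)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "detect": _stage_detect,
    "biotic": _stage_biotic,
    "cohort": _stage_cohort,
    "stats": _stage_stats,
}


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = ALL_STAGES,
) -> dict:
    """Run the selected stages and return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    store = _Store(config=config, outdir=outdir)

    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](store)
        except Exception as exc:  # noqa: BLE001 - manifest must name the stage
            raise StageError(stage, exc) from exc

    inputs = {}
    for name in ("temperature_csv", "salinity_csv", "survey_csv"):
        path = getattr(config, name)
        if path is not None and Path(path).exists():
            inputs[name] = _sha256(Path(path))
    outputs = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*.csv"))
    }
    manifest = {
        "package": "fjordlink",
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "parameters": config.resolved(),
        "input_digests": inputs,
        "output_digests": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
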