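"""End-to-end orchestration: weather -> chill -> hardiness -> budbreak ->
damage -> risk, plus evaluation against observations, with CSV/JSON outputs.

Output layout (one directory per site): ``chill.csv``,
``hardiness_<cultivar>.csv``, ``events_<cultivar>.csv``, ``predictions.csv``,
``risk.csv`` and ``report.json``, with stable column order so reruns are
byte-identical under the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .budbreak import BudbreakPrediction, ObservationConvention
from .chill import ChillSeries, accumulate_chill
from .damage import DamageRun, simulate_with_damage
from .errors import ConfigError
from .evaluation import (
    FitStats,
    ObservationRecord,
    fit_stats,
    match_predictions,
)
from .hardiness import DEFAULT_START, SpringFloorConfig
from .params import CULTIVARS, load_params
from .risk_metrics import RiskSummary, margins_for_season, summarize_risk
from .weather import (
    DormantSeason,
    SiteSeries,
    mean_dormant_season_temperature,
    read_daily_weather,
    season_hourly_temperatures,
    split_seasons,
)

log = logging.getLogger("budfreeze")


@dataclass(frozen=True)
class SiteConfig:
    site_id: str
    latitude_deg: float
    weather_csv: str


@dataclass(frozen=True)
class RunConfig:
    sites: list[SiteConfig]
    cultivars: tuple[str, ...] = CULTIVARS
    convention: ObservationConvention = ObservationConvention.BBCH07_50
    damage_correction: bool = True
    chill_shift_c: float = 0.0
    params_csv: str | None = None
    floor: SpringFloorConfig = field(default_factory=SpringFloorConfig)
    integration_start: tuple[int, int] = DEFAULT_START
    mdst_method: str = "midpoint"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.cultivars) - set(CULTIVARS)
        if unknown:
            raise ConfigError(f"unknown cultivars: {sorted(unknown)}")
        if not self.sites:
            raise ConfigError("config lists no sites")
        if self.params_csv is not None and not Path(self.params_csv).exists():
            raise ConfigError(f"params_csv not found: {self.params_csv}")
        for site in self.sites:
            if not Path(site.weather_csv).exists():
                raise ConfigError(f"weather_csv not found: {site.weather_csv}")


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration (schema_version 1)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    version = raw.get("schema_version", 1)
    if version != 1:
        raise ConfigError(f"unsupported schema_version {version}")
    try:
        sites = [
            SiteConfig(
                site_id=str(s["site_id"]),
                latitude_deg=float(s["latitude_deg"]),
                weather_csv=str(s["weather_csv"]),
            )
            for s in raw["sites"]
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid sites entry ({exc})") from exc
    floors = raw.get("floors", {})
    kwargs = dict(
        sites=sites,
        cultivars=tuple(raw.get("cultivars", CULTIVARS)),
        convention=ObservationConvention(raw.get("convention", "BBCH07_50")),
        damage_correction=bool(raw.get("damage_correction", True)),
        chill_shift_c=float(raw.get("chill_shift_c", 0.0)),
        params_csv=raw.get("params_csv"),
        floor=SpringFloorConfig(
            floor10_c=float(floors.get("p10", -1.2)),
            floor50_c=float(floors.get("p50", -2.5)),
            floor90_c=float(floors.get("p90", -3.8)),
        ),
        mdst_method=str(raw.get("mdst_method", "midpoint")),
        out_dir=raw.get("out_dir"),
        seed=int(raw.get("seed", 0)),
    )
    if "integration_start" in raw:
        month, day = str(raw["integration_start"]).split("-")
        kwargs["integration_start"] = (int(month), int(day))
    return RunConfig(**kwargs)


@dataclass(frozen=True)
class SeasonResult:
    """All per-season products for one site/cultivar."""

    site_id: str
    cultivar: str
    season_year: int
    mdst_c: float
    chill: ChillSeries
    run: DamageRun
    risk: RiskSummary

    @property
    def initial(self) -> BudbreakPrediction:
        return self.run.initial

    @property
    def budbreak(self) -> BudbreakPrediction:
        """The prediction downstream consumers should use (FDC when damage
        correction is on, otherwise the initial one)."""
        return self.run.fdc if self.run.fdc.corrected else self.run.initial


def run_season(
    config: RunConfig,
    season: DormantSeason,
    table,
    hourly: np.ndarray | None = None,
) -> list[SeasonResult]:
    chill = accumulate_chill(season, shift_c=config.chill_shift_c,
                             hourly_temp_c=hourly)
    mdst = mean_dormant_season_temperature(season, method=config.mdst_method)
    results = []
    for cultivar in config.cultivars:
        run = simulate_with_damage(
            cultivar, season, chill,
            convention=config.convention,
            floor=config.floor,
            table=table,
            start=config.integration_start,
        )
        if not config.damage_correction:
            run = DamageRun(
                season=run.season, cultivar=run.cultivar,
                threshold_c=run.threshold_c, initial=run.initial,
                fdc=run.initial, events=run.events,
                adjusted_bounded=run.adjusted_bounded,
                adjusted_projected=run.adjusted_projected,
                undamaged_projected=run.undamaged_projected,
            )
        margins = margins_for_season(
            season.dates, season.tmin_c, run.adjusted_bounded.ch50_c,
            season.season_year,
        )
        risk = summarize_risk(season.site_id, cultivar, season.season_year,
                              mdst, margins)
        results.append(
            SeasonResult(
                site_id=season.site_id,
                cultivar=cultivar,
                season_year=season.season_year,
                mdst_c=mdst,
                chill=chill,
                run=run,
                risk=risk,
            )
        )
    return results


def run_site(config: RunConfig, site: SiteConfig) -> list[SeasonResult]:
    """Run the full pipeline over every complete season of one site."""
    table = load_params(config.params_csv) if config.params_csv else None
    series = read_daily_weather(site.weather_csv, site.site_id,
                                site.latitude_deg)
    return run_series(config, series, table)


def run_series(config: RunConfig, series: SiteSeries,
               table=None) -> list[SeasonResult]:
    seasons = split_seasons(series)
    if not seasons:
        log.warning("site %s: no complete 1 Jul-30 Jun season", series.site_id)
    results: list[SeasonResult] = []
    for season in seasons:
        hourly = season_hourly_temperatures(season)
        results.extend(run_season(config, season, table, hourly=hourly))
        log.info("site %s season %d: done", series.site_id, season.season_year)
    if config.out_dir:
        write_outputs(Path(config.out_dir) / series.site_id, results, config)
    return results


def predictions_frame(results: list[SeasonResult],
                      config: RunConfig) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "site_id": r.site_id,
                "cultivar": r.cultivar,
                "season_year": r.season_year,
                "convention": config.convention.value,
                "threshold_c": r.run.threshold_c,
                "doy_initial": r.run.initial.doy,
                "doy_fdc": r.run.fdc.doy,
                "status": r.budbreak.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "cultivar", "season_year", "convention",
                 "threshold_c", "doy_initial", "doy_fdc", "status"],
    )


def risk_frame(results: list[SeasonResult]) -> pd.DataFrame:
    rows = [
        {
            "site_id": r.site_id,
            "cultivar": r.cultivar,
            "season_year": r.season_year,
            "mdst_c": round(r.mdst_c, 6),
            "band": r.risk.band,
            "n_risk_days": r.risk.n_risk_days,
            "n_near_miss_days": r.risk.n_near_miss_days,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["site_id", "cultivar", "season_year", "mdst_c", "band",
                 "n_risk_days", "n_near_miss_days"],
    )


def write_outputs(out_dir: Path, results: list[SeasonResult],
                  config: RunConfig) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chill_parts = []
    seen_years = set()
    for r in results:
        if r.season_year not in seen_years:
            seen_years.add(r.season_year)
            frame = r.chill.to_frame().round(6)
            frame.insert(0, "season_year", r.season_year)
            chill_parts.append(frame)
    if chill_parts:
        pd.concat(chill_parts).rename_axis("date").to_csv(
            out_dir / "chill.csv", float_format="%.6f"
        )
    for cultivar in config.cultivars:
        sub = [r for r in results if r.cultivar == cultivar]
        if not sub:
            continue
        traj_parts = []
        event_parts = []
        for r in sub:
            season = r.run.season
            frame = pd.DataFrame(
                {
                    "tmin_c": season.tmin_c,
                    "tmax_c": season.tmax_c,
                    "chill_portions_cum": r.chill.portions_cum,
                    "ch10_c": r.run.adjusted_bounded.ch10_c,
                    "ch50_c": r.run.adjusted_bounded.ch50_c,
                    "ch90_c": r.run.adjusted_bounded.ch90_c,
                },
                index=season.dates,
            ).round(6)
            frame.insert(0, "season_year", r.season_year)
            frame["mode"] = "bounded"
            traj_parts.append(frame)
            events = r.run.events_frame()
            if len(events):
                events.insert(0, "season_year", r.season_year)
                event_parts.append(events)
        pd.concat(traj_parts).rename_axis("date").to_csv(
            out_dir / f"hardiness_{cultivar}.csv", float_format="%.6f"
        )
        if event_parts:
            pd.concat(event_parts).round(6).to_csv(
                out_dir / f"events_{cultivar}.csv", index=False,
                float_format="%.6f",
            )
    predictions_frame(results, config).to_csv(
        out_dir / "predictions.csv", index=False
    )
    risk_frame(results).to_csv(out_dir / "risk.csv", index=False)


def evaluate_run(
    results: list[SeasonResult],
    observations: list[ObservationRecord],
    r2_method: str = "pearson",
) -> dict:
    """Evaluation report with the damage-based grouping.

    Groups: ``overall`` (the adopted predictions), ``no_damage`` (seasons
    without predicted pre-budbreak events), ``damaged_uncorrected`` and
    ``damaged_corrected`` (seasons with events, before/after correction).
    """
    if not observations:
        raise ValueError("no observations supplied")

    def damaged(result: SeasonResult) -> bool:
        cut = result.run.initial.date
        return any(cut is None or ev.date < cut for ev in result.run.events)

    groups = {
        "overall": [(r, r.budbreak) for r in results],
        "no_damage": [(r, r.run.initial) for r in results if not damaged(r)],
        "damaged_uncorrected": [
            (r, r.run.initial) for r in results if damaged(r)
        ],
        "damaged_corrected": [(r, r.run.fdc) for r in results if damaged(r)],
    }
    report: dict = {"groups": {}}
    matched_any = 0
    for name, pairs in groups.items():
        preds = [p for _, p in pairs]
        pred, obs, n_failed, n_unmatched = match_predictions(preds, observations)
        entry: dict = {"n_failed": n_failed, "n_unmatched": n_unmatched,
                       "n": len(pred)}
        if len(pred):
            stats = fit_stats(pred, obs, r2_method=r2_method)
            entry.update(
                rmse_days=stats.rmse_days,
                bias_days=stats.bias_days,
                r2=stats.r2,
            )
        report["groups"][name] = entry
        matched_any += len(pred)
    if matched_any == 0:
        raise ValueError("zero observation records matched the run results")
    return report


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
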