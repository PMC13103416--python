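"""Daily bud cold-hardiness integration per cultivar and percentile.

Cold hardiness CH is a lethal temperature in C (more negative = hardier) and
follows CH(d) = CH(d-1) - gain(d) + loss(d), where

* ``gain`` (acclimation) responds to how far the daily minimum sits below a
  chill-dependent ceiling, scaled down as CH approaches the cultivar's
  maximum-hardiness bound;
* ``loss`` (deacclimation) is a temperature response evaluated at the daily
  minimum and maximum, gated by a logistic deacclimation potential that rises
  from 0 (no chill) to 1 (chill-satisfied).

In ``projected`` mode CH may rise freely into positive values (used for
budbreak extraction); in ``bounded`` mode CH is capped at a spring floor
representing the minimum hardiness of growing green tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chill import ChillSeries
from .errors import AlignmentError, ParameterError
from .params import CultivarParams, params_for
from .weather import DormantSeason

#: integration begins on this (month, day) within the season, by default
DEFAULT_START = (9, 1)

MODES = ("projected", "bounded")


@dataclass(frozen=True)
class SpringFloorConfig:
    """Per-percentile minimum hardiness of growing tissue (bounded mode cap).

    Defaults sit in the 0 to -4 C range established by controlled freeze
    tests on newly emerged green tissue; they are configuration, not model
    constants.
    """

    floor10_c: float = -1.2
    floor50_c: float = -2.5
    floor90_c: float = -3.8

    def __post_init__(self) -> None:
        if not self.floor10_c >= self.floor50_c >= self.floor90_c:
            raise ParameterError("spring floors must satisfy f10 >= f50 >= f90")

    def floor_for(self, percentile: int) -> float:
        return {10: self.floor10_c, 50: self.floor50_c, 90: self.floor90_c}[
            percentile
        ]


def deacclimation_potential(params: CultivarParams, chill_portions) -> np.ndarray:
    """Logistic fraction in [0, 1] of the deacclimation rate realized."""
    cp = np.asarray(chill_portions, dtype=float)
    if (cp < 0).any():
        raise ValueError("chill portions must be >= 0")
    return 1.0 / (
        1.0 + np.exp(-params.pot_steepness * (cp - params.pot_chill_half))
    )


def acclimation_ceiling(params: CultivarParams, chill_portions) -> np.ndarray:
    """Warmest daily minimum that still elicits acclimation; falls as chill
    accumulates."""
    cp = np.asarray(chill_portions, dtype=float)
    return params.acc_temp_max_c - params.acc_chill_decay * cp


def acclimation_gain(params: CultivarParams, chill_portions: float,
                     tmin_c: float, ch_prev_c: float) -> float:
    """Hardiness gained in one day, in C (>= 0).

    Zero once the bud sits at its maximum-hardiness bound; larger for colder
    minima; smaller as chill accumulates (the eliciting ceiling drops).
    """
    ceiling = float(acclimation_ceiling(params, chill_portions))
    driving = max(0.0, ceiling - tmin_c)
    headroom = (ch_prev_c - params.ch_max_c) / (0.0 - params.ch_max_c)
    headroom = min(max(headroom, 0.0), 1.0)
    return params.acc_rate * driving * headroom


def deacclimation_loss(params: CultivarParams, chill_portions: float,
                       tmin_c: float, tmax_c: float) -> float:
    """Hardiness lost in one day, in C (>= 0).

    Temperature response above ``dea_temp_base_c`` evaluated as the mean of
    the daily-minimum and daily-maximum half-day contributions, multiplied by
    the deacclimation potential.
    """
    if tmin_c > tmax_c:
        raise ValueError("tmin_c > tmax_c")
    potential = float(deacclimation_potential(params, chill_portions))
    response = 0.5 * (
        max(0.0, tmin_c - params.dea_temp_base_c)
        + max(0.0, tmax_c - params.dea_temp_base_c)
    )
    return potential * params.dea_rate * response


def integration_start_date(season: DormantSeason,
                           start: tuple[int, int] = DEFAULT_START) -> pd.Timestamp:
    month, day = start
    year = season.season_year - 1 if month >= 7 else season.season_year
    return pd.Timestamp(year, month, day)


def simulate_hardiness(
    params: CultivarParams,
    season: DormantSeason,
    chill: ChillSeries,
    mode: str = "projected",
    floor: SpringFloorConfig | None = None,
    start: tuple[int, int] = DEFAULT_START,
) -> np.ndarray:
    """Integrate one percentile's hardiness over a season.

    Returns an array aligned with ``season.dates``; NaN before the
    integration start date.  The state is clamped at the cultivar's
    maximum-hardiness bound, and additionally capped at the spring floor in
    ``bounded`` mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if len(chill) != len(season) or not (chill.dates == season.dates).all():
        raise AlignmentError("chill series not aligned with season weather")
    floor = floor if floor is not None else SpringFloorConfig()
    floor_c = floor.floor_for(params.percentile)
    tmin = season.tmin_c
    tmax = season.tmax_c
    cp = chill.portions_cum
    start_ts = integration_start_date(season, start)
    start_idx = int(np.searchsorted(season.dates, start_ts))
    out = np.full(len(season), np.nan)
    ch = params.ch_init_c
    for d in range(start_idx, len(season)):
        gain = acclimation_gain(params, cp[d], tmin[d], ch)
        loss = deacclimation_loss(params, cp[d], tmin[d], tmax[d])
        ch = ch - gain + loss
        ch = max(ch, params.ch_max_c)
        if mode == "bounded":
            ch = min(ch, floor_c)
        out[d] = ch
    return out


@dataclass(frozen=True)
class HardinessTrajectory:
    """Aligned 10th/50th/90th percentile hardiness for one season."""

    site_id: str
    cultivar: str
    season_year: int
    dates: pd.DatetimeIndex
    ch10_c: np.ndarray = field(repr=False)
    ch50_c: np.ndarray = field(repr=False)
    ch90_c: np.ndarray = field(repr=False)
    mode: str = "projected"
    chill: ChillSeries | None = None

    def __post_init__(self) -> None:
        n = len(self.dates)
        if not (len(self.ch10_c) == len(self.ch50_c) == len(self.ch90_c) == n):
            raise AlignmentError("percentile trajectories misaligned")
        valid = ~np.isnan(self.ch50_c)
        if not (
            (self.ch10_c[valid] >= self.ch50_c[valid] - 1e-9).all()
            and (self.ch50_c[valid] >= self.ch90_c[valid] - 1e-9).all()
        ):
            raise ParameterError(
                "percentile ordering violated (ch10 >= ch50 >= ch90); "
                "check the parameter transcription"
            )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "ch10_c": self.ch10_c,
                "ch50_c": self.ch50_c,
                "ch90_c": self.ch90_c,
            },
            index=self.dates,
        )
        frame["mode"] = self.mode
        return frame


def simulate_all_percentiles(
    cultivar: str,
    season: DormantSeason,
    chill: ChillSeries,
    mode: str = "projected",
    floor: SpringFloorConfig | None = None,
    table=None,
    start: tuple[int, int] = DEFAULT_START,
) -> HardinessTrajectory:
    """Simulate all three percentiles and enforce the ordering invariant."""
    series = {
        pct: simulate_hardiness(
            params_for(cultivar, pct, table), season, chill, mode, floor, start
        )
        for pct in (10, 50, 90)
    }
    return HardinessTrajectory(
        site_id=season.site_id,
        cultivar=cultivar,
        season_year=season.season_year,
        dates=season.dates,
        ch10_c=series[10],
        ch50_c=series[50],
        ch90_c=series[90],
        mode=mode,
        chill=chill,
    )
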