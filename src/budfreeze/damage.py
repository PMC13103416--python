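"""Freeze-damage detection, percent-damage interpolation and survivor
adjustment of the percentile cold-hardiness trajectories.

A freeze event is a day whose minimum air temperature falls below the
predicted 10th-percentile hardiness.  The percent of the existing bud
population damaged is a piecewise-linear interpolation on the quantile curve
through (10, CH10), (50, CH50), (90, CH90), capped at 90%.  After an event
the three percentile states are replaced by the quantiles of the surviving
(hardier) population: the survivor's percentile p sits at position
d + p(100-d)/100 of the pre-event population, and the pre-event quantile
curve is linearly interpolated/extrapolated at that position.

Freeze-damage-corrected (FDC) budbreak is re-extracted from the adjusted
projected 50th percentile; only events before the initially predicted
budbreak move the prediction, later events are recorded for risk analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .budbreak import (
    BudbreakPrediction,
    ObservationConvention,
    extract_budbreak,
    threshold_for,
)
from .chill import ChillSeries
from .errors import AlignmentError, DegenerateSpreadError
from .hardiness import (
    DEFAULT_START,
    HardinessTrajectory,
    SpringFloorConfig,
    acclimation_gain,
    deacclimation_loss,
    integration_start_date,
    simulate_all_percentiles,
)
from .params import params_for
from .weather import DormantSeason

_SPREAD_EPS = 1e-9


def detect_freeze_event(tmin_c: float, ch10_c: float,
                        at_equal: bool = False) -> bool:
    """True iff the day's minimum is below the 10th-percentile hardiness.

    Strict inequality by default: at ``tmin == ch10`` the interpolation
    yields exactly the 10% already nominally below the 10th percentile, so
    equality is treated as no event (switchable via ``at_equal``).
    """
    return tmin_c <= ch10_c if at_equal else tmin_c < ch10_c


def percent_damage(tmin_c: float, ch10_c: float, ch50_c: float,
                   ch90_c: float) -> float:
    """Percent of the existing population damaged by a freeze at ``tmin_c``.

    Band (CH50 <= Tmin <= CH10): 10 + (50-10)/(CH50-CH10) * (Tmin-CH10).
    Band (Tmin < CH50):  min(50 + (90-50)/(CH90-CH50) * (Tmin-CH50), 90).
    The two bands agree exactly at the seam Tmin == CH50.
    """
    if not ch10_c >= ch50_c >= ch90_c:
        raise ValueError("percentile ordering ch10 >= ch50 >= ch90 violated")
    if ch10_c - ch50_c < _SPREAD_EPS or ch50_c - ch90_c < _SPREAD_EPS:
        raise DegenerateSpreadError(
            f"degenerate percentile spread ({ch10_c}, {ch50_c}, {ch90_c})"
        )
    if tmin_c > ch10_c:
        raise ValueError("percent_damage requires tmin_c <= ch10_c")
    if tmin_c >= ch50_c:
        return 10.0 + (50.0 - 10.0) / (ch50_c - ch10_c) * (tmin_c - ch10_c)
    return min(50.0 + (90.0 - 50.0) / (ch90_c - ch50_c) * (tmin_c - ch50_c),
               90.0)


@dataclass(frozen=True)
class AdjustedPercentiles:
    """Survivor-population percentile hardiness after a freeze event."""

    ch10_adj_c: float
    ch50_adj_c: float
    ch90_adj_c: float


def adjust_percentiles(ch10_c: float, ch50_c: float, ch90_c: float,
                       pct_damage: float) -> AdjustedPercentiles:
    """Quantiles of the surviving population after ``pct_damage`` % losses.

    With d = pct_damage, the survivor's percentile p maps to position
    d + p(100-d)/100 of the pre-event population; the pre-event quantile
    curve is evaluated there segment-wise.  CH10* uses the upper segment's
    slope for d <= 50 and the (CH90-CH10)/80 chord beyond; at d = 0 the
    adjustment is the identity.
    """
    if not ch10_c >= ch50_c >= ch90_c:
        raise ValueError("percentile ordering ch10 >= ch50 >= ch90 violated")
    if not 0.0 <= pct_damage <= 90.0:
        raise ValueError("pct_damage must be within [0, 90]")
    d = pct_damage
    pos = lambda p: d + p * (100.0 - d) / 100.0  # noqa: E731
    ch50_adj = ch50_c + (ch90_c - ch50_c) / 40.0 * (pos(50.0) - 50.0)
    ch90_adj = ch90_c + (ch90_c - ch50_c) / 40.0 * (pos(90.0) - 90.0)
    if d <= 50.0:
        ch10_adj = ch10_c + (ch50_c - ch10_c) / 40.0 * (pos(10.0) - 10.0)
    else:
        ch10_adj = ch10_c + (ch90_c - ch10_c) / 80.0 * (pos(10.0) - 10.0)
    return AdjustedPercentiles(ch10_adj, ch50_adj, ch90_adj)


@dataclass(frozen=True)
class FreezeEvent:
    """A detected damage day with pre-event state and survivor adjustment."""

    date: pd.Timestamp
    tmin_c: float
    ch10_c: float
    ch50_c: float
    ch90_c: float
    pct_damage: float
    surviving_fraction_cum: float
    ch10_adj_c: float
    ch50_adj_c: float
    ch90_adj_c: float


@dataclass(frozen=True)
class DamageRun:
    """Everything produced by a damage-aware season simulation."""

    season: DormantSeason
    cultivar: str
    threshold_c: float
    initial: BudbreakPrediction
    fdc: BudbreakPrediction
    events: list[FreezeEvent]
    adjusted_bounded: HardinessTrajectory = field(repr=False)
    adjusted_projected: HardinessTrajectory = field(repr=False)
    undamaged_projected: HardinessTrajectory = field(repr=False)

    def events_frame(self) -> pd.DataFrame:
        cols = [
            "date", "tmin_c", "ch10_c", "ch50_c", "ch90_c", "pct_damage",
            "surviving_fraction_cum", "ch10_adj_c", "ch50_adj_c", "ch90_adj_c",
        ]
        return pd.DataFrame(
            [{c: getattr(ev, c) for c in cols} for ev in self.events],
            columns=cols,
        )


def _step(params, cp, tmin, tmax, ch_prev):
    gain = acclimation_gain(params, cp, tmin, ch_prev)
    loss = deacclimation_loss(params, cp, tmin, tmax)
    return ch_prev - gain + loss


def simulate_with_damage(
    cultivar: str,
    season: DormantSeason,
    chill: ChillSeries,
    convention: ObservationConvention = ObservationConvention.BBCH07_50,
    floor: SpringFloorConfig | None = None,
    threshold_c: float | None = None,
    table=None,
    start: tuple[int, int] = DEFAULT_START,
    detect_at_equal: bool = False,
) -> DamageRun:
    """Damage-aware simulation of all three percentiles for one season.

    Bounded and projected tracks are advanced jointly from the same events:
    detection and percent damage use the bounded (realistic) trajectory, the
    projected track receives the same adjustments for events that precede
    the initially predicted budbreak, and FDC budbreak is extracted from the
    adjusted projected 50th percentile.  Surviving fraction multiplies by
    (1 - damage/100) per event.
    """
    if len(chill) != len(season) or not (chill.dates == season.dates).all():
        raise AlignmentError("chill series not aligned with season weather")
    floor = floor if floor is not None else SpringFloorConfig()
    if threshold_c is None:
        threshold_c = threshold_for(cultivar, convention)
    pcts = (10, 50, 90)
    par = {p: params_for(cultivar, p, table) for p in pcts}
    floors = {p: floor.floor_for(p) for p in pcts}

    undamaged = simulate_all_percentiles(
        cultivar, season, chill, "projected", floor, table, start
    )
    initial = extract_budbreak(undamaged, threshold_c, corrected=False)
    initial_bb_date = initial.date  # None if FAILED

    tmin = season.tmin_c
    tmax = season.tmax_c
    cp = chill.portions_cum
    dates = season.dates
    start_idx = int(np.searchsorted(dates, integration_start_date(season, start)))
    n = len(season)
    proj = {p: np.full(n, np.nan) for p in pcts}
    bound = {p: np.full(n, np.nan) for p in pcts}
    pstate = {p: par[p].ch_init_c for p in pcts}
    bstate = {p: par[p].ch_init_c for p in pcts}
    events: list[FreezeEvent] = []
    surviving = 1.0

    for d in range(start_idx, n):
        for p in pcts:
            pstate[p] = max(_step(par[p], cp[d], tmin[d], tmax[d], pstate[p]),
                            par[p].ch_max_c)
            bstate[p] = min(
                max(_step(par[p], cp[d], tmin[d], tmax[d], bstate[p]),
                    par[p].ch_max_c),
                floors[p],
            )
        if detect_freeze_event(tmin[d], bstate[10], at_equal=detect_at_equal):
            pct = percent_damage(tmin[d], bstate[10], bstate[50], bstate[90])
            adj = adjust_percentiles(bstate[10], bstate[50], bstate[90], pct)
            surviving *= 1.0 - pct / 100.0
            events.append(
                FreezeEvent(
                    date=dates[d],
                    tmin_c=float(tmin[d]),
                    ch10_c=bstate[10], ch50_c=bstate[50], ch90_c=bstate[90],
                    pct_damage=pct,
                    surviving_fraction_cum=surviving,
                    ch10_adj_c=adj.ch10_adj_c,
                    ch50_adj_c=adj.ch50_adj_c,
                    ch90_adj_c=adj.ch90_adj_c,
                )
            )
            bstate = {
                10: max(adj.ch10_adj_c, par[10].ch_max_c),
                50: max(adj.ch50_adj_c, par[50].ch_max_c),
                90: max(adj.ch90_adj_c, par[90].ch_max_c),
            }
            moves_budbreak = initial_bb_date is None or dates[d] < initial_bb_date
            if moves_budbreak:
                padj = adjust_percentiles(pstate[10], pstate[50], pstate[90],
                                          pct)
                pstate = {
                    10: max(padj.ch10_adj_c, par[10].ch_max_c),
                    50: max(padj.ch50_adj_c, par[50].ch_max_c),
                    90: max(padj.ch90_adj_c, par[90].ch_max_c),
                }
        for p in pcts:
            proj[p][d] = pstate[p]
            bound[p][d] = bstate[p]

    common = dict(site_id=season.site_id, cultivar=cultivar,
                  season_year=season.season_year, dates=dates, chill=chill)
    adjusted_projected = HardinessTrajectory(
        ch10_c=proj[10], ch50_c=proj[50], ch90_c=proj[90],
        mode="projected", **common,
    )
    adjusted_bounded = HardinessTrajectory(
        ch10_c=bound[10], ch50_c=bound[50], ch90_c=bound[90],
        mode="bounded", **common,
    )
    fdc = extract_budbreak(adjusted_projected, threshold_c, corrected=True)
    return DamageRun(
        season=season,
        cultivar=cultivar,
        threshold_c=threshold_c,
        initial=initial,
        fdc=fdc,
        events=events,
        adjusted_bounded=adjusted_bounded,
        adjusted_projected=adjusted_projected,
        undamaged_projected=undamaged,
    )
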