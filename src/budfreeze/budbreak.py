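"""Budbreak extraction from projected cold-hardiness trajectories.

Budbreak is predicted on the first day the projected 50th-percentile
hardiness reaches a cultivar- and convention-specific threshold; if the
trajectory never reaches it by 30 June the prediction is FAILED (a
first-class outcome, not an error).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hardiness import HardinessTrajectory


class ObservationConvention(enum.Enum):
    """How field budbreak was recorded."""

    BBCH07_50 = "BBCH07_50"    # 50% of buds at green shoot tips visible
    BBCH05_50 = "BBCH05_50"    # 50% of buds at wool stage
    BBCH05_FIRST = "BBCH05_first"  # first bud at wool stage


#: threshold (C) on projected ch50 at which budbreak is declared
_THRESHOLDS: dict[tuple[str, ObservationConvention], float] = {
    ("Cabernet-Sauvignon", ObservationConvention.BBCH07_50): 10.0,
    ("Riesling", ObservationConvention.BBCH07_50): 10.0,
    ("Concord", ObservationConvention.BBCH07_50): 5.0,
    ("Cabernet-Sauvignon", ObservationConvention.BBCH05_50): 5.0,
    ("Riesling", ObservationConvention.BBCH05_50): 5.0,
    ("Cabernet-Sauvignon", ObservationConvention.BBCH05_FIRST): 0.0,
    ("Riesling", ObservationConvention.BBCH05_FIRST): 0.0,
}


def threshold_for(cultivar: str, convention: ObservationConvention) -> float:
    """Cold hardiness at budbreak, in C, for a cultivar and convention.

    The earlier-stage conventions only have adjusted thresholds for the two
    V. vinifera cultivars; Concord under a BBCH05 convention requires an
    explicit config override and raises here.
    """
    if not isinstance(convention, ObservationConvention):
        convention = ObservationConvention(convention)
    try:
        return _THRESHOLDS[(cultivar, convention)]
    except KeyError:
        raise ParameterError(
            f"no budbreak threshold for cultivar={cultivar!r} "
            f"convention={convention.value}"
        ) from None


@dataclass(frozen=True)
class BudbreakPrediction:
    """Threshold-crossing day for one site/cultivar/season."""

    site_id: str
    cultivar: str
    season_year: int
    threshold_c: float
    status: str                 # "OK" | "FAILED"
    doy: int | None = None      # day-of-year on the spring calendar year
    date: pd.Timestamp | None = None
    corrected: bool = False     # freeze-damage-corrected?

    @property
    def failed(self) -> bool:
        return self.status == "FAILED"


def extract_budbreak(
    trajectory: HardinessTrajectory,
    threshold_c: float,
    corrected: bool = False,
) -> BudbreakPrediction:
    """First day the projected ch50 is at or above ``threshold_c``.

    Daily resolution, no sub-day interpolation; the search window ends at the
    season's last day (30 June).  A bounded-mode trajectory is rejected: its
    spring floor would prevent the crossing.
    """
    if trajectory.mode != "projected":
        raise ValueError(
            "budbreak extraction requires a projected-mode trajectory"
        )
    ch50 = trajectory.ch50_c
    hit = np.nonzero(~np.isnan(ch50) & (ch50 >= threshold_c))[0]
    common = dict(
        site_id=trajectory.site_id,
        cultivar=trajectory.cultivar,
        season_year=trajectory.season_year,
        threshold_c=threshold_c,
        corrected=corrected,
    )
    if len(hit) == 0:
        return BudbreakPrediction(status="FAILED", **common)
    date = trajectory.dates[hit[0]]
    doy = (date - pd.Timestamp(trajectory.season_year, 1, 1)).days + 1
    return BudbreakPrediction(status="OK", doy=int(doy), date=date, **common)
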