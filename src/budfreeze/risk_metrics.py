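"""Dormant-season frost-risk indicators.

Safety margin = Tmin - CH50 (damage-adjusted, bounded trajectory); a margin
at or below zero predicts at least 50% freeze damage and counts as a risk
day, margins in (0, 2] C count as near misses.  Seasons are classified into
four risk bands by their mean dormant-season temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SeasonGapError

NEAR_MISS_UPPER_C = 2.0


def safety_margin(tmin_c, ch50_c):
    """Daily safety margin(s): tmin_c - ch50_c (element-wise)."""
    return np.asarray(tmin_c, dtype=float) - np.asarray(ch50_c, dtype=float)


@dataclass(frozen=True)
class SafetyMarginSeries:
    """Per-day safety margins across one simulated season."""

    season_year: int
    dates: pd.DatetimeIndex
    margin_c: np.ndarray

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.margin_c):
            raise SeasonGapError("safety-margin series misaligned with dates")


def margins_for_season(dates: pd.DatetimeIndex, tmin_c: np.ndarray,
                       ch50_c: np.ndarray, season_year: int
                       ) -> SafetyMarginSeries:
    """Margins over the simulated (non-NaN hardiness) days of a season."""
    ch50_c = np.asarray(ch50_c, dtype=float)
    valid = ~np.isnan(ch50_c)
    return SafetyMarginSeries(
        season_year=season_year,
        dates=dates[valid],
        margin_c=safety_margin(np.asarray(tmin_c, float)[valid], ch50_c[valid]),
    )


def count_risk_days(margins: SafetyMarginSeries) -> int:
    """Number of days with safety margin <= 0."""
    if np.isnan(margins.margin_c).any():
        raise SeasonGapError("safety margins contain missing values")
    return int((margins.margin_c <= 0.0).sum())


def count_near_miss_days(margins: SafetyMarginSeries) -> int:
    """Number of days with safety margin in (0, 2]."""
    if np.isnan(margins.margin_c).any():
        raise SeasonGapError("safety margins contain missing values")
    m = margins.margin_c
    return int(((m > 0.0) & (m <= NEAR_MISS_UPPER_C)).sum())


def classify_mdst_band(mdst_c: float) -> int:
    """Risk band 1..4 from mean dormant-season temperature.

    1: mdst < 1 (high risk); 2: 1 <= mdst <= 3; 3: 3 < mdst <= 8;
    4: mdst > 8 (low risk).  Boundary values belong to the lower band.
    """
    if mdst_c < 1.0:
        return 1
    if mdst_c <= 3.0:
        return 2
    if mdst_c <= 8.0:
        return 3
    return 4


@dataclass(frozen=True)
class RiskSummary:
    site_id: str
    cultivar: str
    season_year: int
    mdst_c: float
    band: int
    n_risk_days: int
    n_near_miss_days: int


def summarize_risk(site_id: str, cultivar: str, season_year: int,
                   mdst_c: float, margins: SafetyMarginSeries) -> RiskSummary:
    return RiskSummary(
        site_id=site_id,
        cultivar=cultivar,
        season_year=season_year,
        mdst_c=float(mdst_c),
        band=classify_mdst_band(mdst_c),
        n_risk_days=count_risk_days(margins),
        n_near_miss_days=count_near_miss_days(margins),
    )


def align_to_budbreak(dates: pd.DatetimeIndex, fdc_date) -> np.ndarray:
    """Integer day offsets from the FDC budbreak day (0 = budbreak)."""
    if fdc_date is None:
        raise ValueError(
            "cannot align a season without a successful FDC budbreak"
        )
    return (dates - pd.Timestamp(fdc_date)).days.to_numpy()
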