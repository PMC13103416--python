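"""Dynamic-Model chill portions from hourly temperatures.

Two-step precursor/portion process: an intermediate precursor ``x`` is formed
at low temperatures and destroyed at warm ones; when it reaches 1, a fraction
of it is banked irreversibly as chill portions.  Rate constants below are the
published values used by the canonical implementations of the model.

An optional phase shift ``s`` evaluates the submodel on ``T - s`` so the
temperature-response optimum moves from its native position (~7.5 C at
constant temperature) to native + s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SeasonGapError
from .weather import DormantSeason, season_hourly_temperatures

# Canonical Dynamic Model rate constants (Fishman two-intermediate scheme,
# as used by the standard horticultural implementations).
E0 = 4153.5
E1 = 12888.8
A0 = 139500.0
A1 = 2.567e18
SLP = 1.6
TETMLT = 277.0


@dataclass(frozen=True)
class ChillState:
    """Precursor level and banked portions after some number of hourly steps."""

    precursor_x: float = 0.0
    portions: float = 0.0


def _coefficients(temp_c: np.ndarray):
    """Hourly transfer coefficients (xi, xs, ak1) at temperature(s) in C."""
    tk = np.asarray(temp_c, dtype=float) + 273.0
    ftmprt = SLP * TETMLT * (tk - TETMLT) / tk
    sr = np.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = (A0 / A1) * np.exp((E1 - E0) / tk)
    ak1 = A1 * np.exp(-E1 / tk)
    return xi, xs, ak1


def dynamic_model_step(state: ChillState, hourly_temp_c: float) -> ChillState:
    """Advance the precursor/portion process by one hour.

    When the precursor reaches 1, the fraction ``x * xi`` is banked as
    portions and removed from the precursor pool; banked portions never
    decrease.
    """
    if not np.isfinite(hourly_temp_c):
        raise ValueError("non-finite temperature")
    xi, xs, ak1 = _coefficients(hourly_temp_c)
    e = xs - (xs - state.precursor_x) * np.exp(-ak1)
    if e >= 1.0:
        delta = float(e * xi)
        return ChillState(precursor_x=float(e - delta),
                          portions=state.portions + delta)
    return ChillState(precursor_x=float(e), portions=state.portions)


def chill_portions_hourly(hourly_temp_c: np.ndarray,
                          shift_c: float = 0.0) -> np.ndarray:
    """Cumulative chill portions after each hour of ``hourly_temp_c``."""
    temps = np.asarray(hourly_temp_c, dtype=float)
    if not np.isfinite(temps).all():
        raise ValueError("non-finite temperature in hourly series")
    xi, xs, ak1 = _coefficients(temps - shift_c)
    decay = np.exp(-ak1)
    out = np.empty(len(temps))
    x = 0.0
    total = 0.0
    for i in range(len(temps)):
        e = xs[i] - (xs[i] - x) * decay[i]
        if e >= 1.0:
            delta = e * xi[i]
            total += delta
            x = e - delta
        else:
            x = e
        out[i] = total
    return out


@dataclass(frozen=True)
class ChillSeries:
    """Per-day cumulative chill portions across one dormant season."""

    season_year: int
    dates: pd.DatetimeIndex
    portions_cum: np.ndarray = field(repr=False)
    shift_c: float = 0.0

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.portions_cum):
            raise AlignmentError("chill series misaligned with dates")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chill_portions_cum": self.portions_cum}, index=self.dates
        )


def accumulate_chill(season: DormantSeason, shift_c: float = 0.0,
                     hourly_temp_c: np.ndarray | None = None) -> ChillSeries:
    """Daily cumulative chill portions for a season starting 1 July.

    ``hourly_temp_c`` may be supplied to avoid recomputing the hourly
    interpolation; it must contain 24 values per season day.
    """
    if hourly_temp_c is None:
        hourly_temp_c = season_hourly_temperatures(season)
    hourly_temp_c = np.asarray(hourly_temp_c, dtype=float)
    if len(hourly_temp_c) != 24 * len(season):
        raise SeasonGapError(
            f"expected {24 * len(season)} hourly values, got {len(hourly_temp_c)}"
        )
    cum = chill_portions_hourly(hourly_temp_c, shift_c=shift_c)
    return ChillSeries(
        season_year=season.season_year,
        dates=season.dates,
        portions_cum=cum[23::24].copy(),
        shift_c=shift_c,
    )


def constant_temperature_portions(temp_c: float, n_hours: int,
                                  shift_c: float = 0.0) -> float:
    """Total portions accumulated at a constant temperature."""
    return float(
        chill_portions_hourly(np.full(n_hours, float(temp_c)), shift_c)[-1]
    )


def chill_optimum_sweep(
    lo_c: float = 0.0,
    hi_c: float = 16.0,
    step_c: float = 0.1,
    n_days: int = 60,
    shift_c: float = 0.0,
):
    """Sweep constant temperatures and locate the chill-rate optimum.

    Returns ``(grid, totals, optimum_temp_c)`` where the grid spans
    [lo_c, hi_c] at ``step_c`` resolution and each total is the portion sum
    over ``n_days`` of constant hourly temperature.
    """
    n = int(round((hi_c - lo_c) / step_c))
    grid = lo_c + step_c * np.arange(n + 1)
    totals = np.array(
        [constant_temperature_portions(t, 24 * n_days, shift_c) for t in grid]
    )
    return grid, totals, float(grid[int(np.argmax(totals))])
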