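"""Daily weather input, dormant-season slicing and hourly temperature derivation.

A site's record is a strictly date-ordered table of daily minimum and maximum
temperatures.  Dormant seasons run from 1 July to 30 June of the following
calendar year (Northern Hemisphere only); the season is labelled by the
calendar year containing the spring.  The mean dormant-season temperature
(MDST) is averaged over 1 November through 30 April.

Hourly temperatures are derived from daily extremes with a sine curve during
daylight and a logarithmic decline at night, using day length from standard
solar geometry at the site latitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    SeasonGapError,
    UnsupportedLatitudeError,
    WeatherValidationError,
)

MAX_ABS_TEMP_C = 60.0
#: polar day/night boundary; the sine/log hourly scheme needs sunrise & sunset
MAX_LATITUDE_DEG = 66.6

#: MDST window within a season: 1 Nov (previous year) .. 30 Apr (spring year)
MDST_START = (11, 1)
MDST_END = (4, 30)


@dataclass(frozen=True)
class SiteSeries:
    """A validated, date-sorted daily weather record for one site.

    ``frame`` is indexed by normalized ``DatetimeIndex`` with float columns
    ``tmin_c`` and ``tmax_c``.
    """

    site_id: str
    latitude_deg: float
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise UnsupportedLatitudeError(
                f"latitude {self.latitude_deg} outside [-90, 90]"
            )
        if self.latitude_deg < 0.0:
            raise UnsupportedLatitudeError(
                "Southern-Hemisphere latitudes are not supported: the "
                "1 Jul-30 Jun dormant-season window assumes the Northern "
                "Hemisphere"
            )
        validate_daily_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index


@dataclass(frozen=True)
class DormantSeason:
    """One 1 Jul-30 Jun slice of a site's record.

    ``season_year`` is the calendar year containing the spring; the window is
    1 July (season_year - 1) through 30 June (season_year), inclusive.
    """

    site_id: str
    latitude_deg: float
    season_year: int
    frame: pd.DataFrame = field(repr=False)

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.season_year - 1, 7, 1)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.season_year, 6, 30)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def tmin_c(self) -> np.ndarray:
        return self.frame["tmin_c"].to_numpy()

    @property
    def tmax_c(self) -> np.ndarray:
        return self.frame["tmax_c"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def doy_spring(self) -> np.ndarray:
        """Day-of-year on the spring calendar year axis (1 Jan = 1; autumn
        dates of the previous calendar year come out non-positive)."""
        jan1 = pd.Timestamp(self.season_year, 1, 1)
        return (self.frame.index - jan1).days.to_numpy() + 1


def validate_daily_frame(frame: pd.DataFrame) -> None:
    """Raise :class:`WeatherValidationError` unless ``frame`` is a valid
    date-indexed daily record."""
    for col in ("tmin_c", "tmax_c"):
        if col not in frame.columns:
            raise WeatherValidationError(f"missing column {col!r}")
    if not isinstance(frame.index, pd.DatetimeIndex):
        raise WeatherValidationError("frame must be indexed by date")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise WeatherValidationError(f"duplicated date {dup.date()}")
    if not frame.index.is_monotonic_increasing:
        raise WeatherValidationError("dates are not sorted ascending")
    tmin = frame["tmin_c"].to_numpy(dtype=float)
    tmax = frame["tmax_c"].to_numpy(dtype=float)
    bad = ~(np.isfinite(tmin) & np.isfinite(tmax))
    if bad.any():
        raise WeatherValidationError(
            f"non-finite temperature on {frame.index[bad][0].date()}"
        )
    bad = (np.abs(tmin) > MAX_ABS_TEMP_C) | (np.abs(tmax) > MAX_ABS_TEMP_C)
    if bad.any():
        raise WeatherValidationError(
            f"temperature outside [-60, 60] C on {frame.index[bad][0].date()}"
        )
    bad = tmin > tmax
    if bad.any():
        raise WeatherValidationError(
            f"tmin_c > tmax_c on {frame.index[bad][0].date()}"
        )


def read_daily_weather(path, site_id: str, latitude_deg: float) -> SiteSeries:
    """Read a daily weather CSV (columns ``date``, ``tmin_c``, ``tmax_c``).

    Dates must be ISO-8601.  The result is sorted by date and fully
    validated; any malformed row raises :class:`WeatherValidationError`
    naming the offending date.
    """
    raw = pd.read_csv(path)
    for col in ("date", "tmin_c", "tmax_c"):
        if col not in raw.columns:
            raise WeatherValidationError(f"{path}: missing column {col!r}")
    if "site_id" in raw.columns:
        raw = raw[raw["site_id"].astype(str) == str(site_id)]
        if raw.empty:
            raise WeatherValidationError(f"{path}: no rows for site {site_id!r}")
    try:
        dates = pd.to_datetime(raw["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherValidationError(f"{path}: malformed date ({exc})") from exc
    for col in ("tmin_c", "tmax_c"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            raise WeatherValidationError(
                f"{path}: non-numeric {col} on {dates[bad].iloc[0].date()}"
            )
        raw[col] = vals
    frame = pd.DataFrame(
        {"tmin_c": raw["tmin_c"].to_numpy(float),
         "tmax_c": raw["tmax_c"].to_numpy(float)},
        index=pd.DatetimeIndex(dates).normalize(),
    ).sort_index()
    return SiteSeries(site_id=site_id, latitude_deg=latitude_deg, frame=frame)


def season_window(season_year: int) -> pd.DatetimeIndex:
    return pd.date_range(
        pd.Timestamp(season_year - 1, 7, 1),
        pd.Timestamp(season_year, 6, 30),
        freq="D",
    )


def split_seasons(series: SiteSeries) -> list[DormantSeason]:
    """Slice a site record into fully covered 1 Jul-30 Jun dormant seasons.

    Partial windows (at the record edges, or containing gaps) are skipped.
    """
    if len(series) == 0:
        return []
    idx = series.frame.index
    first_year = idx[0].year
    last_year = idx[-1].year + 1
    out: list[DormantSeason] = []
    for season_year in range(first_year, last_year + 1):
        window = season_window(season_year)
        if window[0] < idx[0] or window[-1] > idx[-1]:
            continue
        sliced = series.frame.reindex(window)
        if sliced["tmin_c"].isna().any():
            continue
        out.append(
            DormantSeason(
                site_id=series.site_id,
                latitude_deg=series.latitude_deg,
                season_year=season_year,
                frame=sliced,
            )
        )
    return out


def mean_dormant_season_temperature(
    season: DormantSeason,
    method: str = "midpoint",
    latitude_deg: float | None = None,
) -> float:
    """MDST: mean temperature over 1 Nov-30 Apr of the season.

    ``method='midpoint'`` uses (tmin + tmax) / 2 per day (default);
    ``method='hourly-mean'`` averages the derived hourly temperatures.
    """
    lo = pd.Timestamp(season.season_year - 1, *MDST_START)
    hi = pd.Timestamp(season.season_year, *MDST_END)
    window = pd.date_range(lo, hi, freq="D")
    sub = season.frame.reindex(window)
    if sub["tmin_c"].isna().any():
        missing = window[sub["tmin_c"].isna()][0]
        raise SeasonGapError(f"missing day {missing.date()} in MDST window")
    if method == "midpoint":
        return float(((sub["tmin_c"] + sub["tmax_c"]) / 2.0).mean())
    if method == "hourly-mean":
        lat = season.latitude_deg if latitude_deg is None else latitude_deg
        hrs = hourly_temperatures(
            sub["tmin_c"].to_numpy(), sub["tmax_c"].to_numpy(), window, lat
        )
        return float(hrs.mean())
    raise ValueError(f"unknown MDST method {method!r}")


# -- hourly interpolation -----------------------------------------------------

def _solar_geometry(dates: pd.DatetimeIndex, latitude_deg: float):
    """Sunrise hour, sunset hour and day length (hours) per day."""
    if abs(latitude_deg) > MAX_LATITUDE_DEG:
        raise UnsupportedLatitudeError(
            f"|latitude| = {abs(latitude_deg)} > {MAX_LATITUDE_DEG}: polar "
            "day/night is unsupported"
        )
    doy = dates.dayofyear.to_numpy()
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    phi = np.deg2rad(latitude_deg)
    cos_h = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    half_day_deg = np.rad2deg(np.arccos(cos_h))
    daylength = 2.0 * half_day_deg / 15.0
    sunrise = 12.0 - daylength / 2.0
    sunset = 12.0 + daylength / 2.0
    return sunrise, sunset, daylength


def hourly_temperatures(
    tmin_c: np.ndarray,
    tmax_c: np.ndarray,
    dates: pd.DatetimeIndex,
    latitude_deg: float,
) -> np.ndarray:
    """Derive 24 hourly temperatures per day from daily extremes.

    Daytime follows a sine from sunrise-anchored Tmin to an afternoon peak,
    T(h) = Tmin + (Tmax - Tmin) * sin(pi * (h - sunrise) / (daylength + 4));
    night-time declines logarithmically from the sunset temperature toward the
    next day's Tmin, reaching it at the next sunrise.  Record edges reuse the
    edge day as its own neighbor.  Returns a flat array of length 24 * n.
    """
    tmin_c = np.asarray(tmin_c, dtype=float)
    tmax_c = np.asarray(tmax_c, dtype=float)
    n = len(tmin_c)
    if n == 0:
        return np.empty(0)
    sunrise, sunset, daylength = _solar_geometry(dates, latitude_deg)
    nightlen = 24.0 - daylength
    t_sunset = tmin_c + (tmax_c - tmin_c) * np.sin(
        np.pi * daylength / (daylength + 4.0)
    )
    # previous-day values, edge day reused at the start
    prev_sunset_h = np.concatenate(([sunset[0]], sunset[:-1]))
    prev_t_sunset = np.concatenate(([t_sunset[0]], t_sunset[:-1]))
    prev_nightlen = np.concatenate(([nightlen[0]], nightlen[:-1]))
    # next-day tmin, edge day reused at the end
    next_tmin = np.concatenate((tmin_c[1:], [tmin_c[-1]]))

    h = np.arange(24.0)[None, :]
    sr = sunrise[:, None]
    ss = sunset[:, None]
    day_frac = np.sin(np.pi * (h - sr) / (daylength[:, None] + 4.0))
    t_day = tmin_c[:, None] + (tmax_c - tmin_c)[:, None] * day_frac

    # evening: hours after today's sunset, declining toward tomorrow's tmin
    n_eve = np.clip(h - ss, 0.0, nightlen[:, None])
    frac_eve = np.log1p(n_eve) / np.log1p(nightlen[:, None])
    t_eve = t_sunset[:, None] - (t_sunset - next_tmin)[:, None] * frac_eve

    # morning: continuation of the previous night, toward today's tmin
    n_mor = np.clip(h + 24.0 - prev_sunset_h[:, None], 0.0,
                    prev_nightlen[:, None])
    frac_mor = np.log1p(n_mor) / np.log1p(prev_nightlen[:, None])
    t_mor = prev_t_sunset[:, None] - (prev_t_sunset - tmin_c)[:, None] * frac_mor

    out = np.where(h < sr, t_mor, np.where(h <= ss, t_day, t_eve))
    return out.ravel()


def interpolate_hourly(
    prev_day: tuple[float, float],
    day: tuple[float, float],
    next_day: tuple[float, float],
    latitude_deg: float,
    date,
) -> np.ndarray:
    """24 hourly temperatures for one day given its neighbors.

    Each of ``prev_day``, ``day``, ``next_day`` is a (tmin_c, tmax_c) pair;
    ``date`` is the calendar date of the middle day.
    """
    date = pd.Timestamp(date)
    dates = pd.DatetimeIndex([date - pd.Timedelta(days=1), date,
                              date + pd.Timedelta(days=1)])
    tmin = np.array([prev_day[0], day[0], next_day[0]], dtype=float)
    tmax = np.array([prev_day[1], day[1], next_day[1]], dtype=float)
    if (tmin > tmax).any():
        raise WeatherValidationError("tmin_c > tmax_c in hourly interpolation")
    return hourly_temperatures(tmin, tmax, dates, latitude_deg)[24:48]


def season_hourly_temperatures(season: DormantSeason) -> np.ndarray:
    """Hourly temperatures for every day of a dormant season (24 per day)."""
    if season.frame["tmin_c"].isna().any():
        missing = season.frame.index[season.frame["tmin_c"].isna()][0]
        raise SeasonGapError(
            f"season {season.season_year}: missing day {missing.date()}"
        )
    return hourly_temperatures(
        season.tmin_c, season.tmax_c, season.dates, season.latitude_deg
    )
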