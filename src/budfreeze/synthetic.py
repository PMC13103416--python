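"""Reproducible synthetic weather and phenology observations.

Daily mean temperature is a sinusoid (annual mean, seasonal amplitude,
configurable coldest day) plus AR(1) noise; tmin/tmax sit half a diurnal
range below/above the mean.  Noise is autocorrelated on daily means so that
multi-day warm/cold spells — which drive dormancy dynamics and freeze
events — actually occur.  All randomness flows from the spec's integer seed
through :func:`numpy.random.default_rng`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .budbreak import BudbreakPrediction, ObservationConvention
from .evaluation import ObservationRecord
from .weather import SiteSeries, split_seasons, mean_dormant_season_temperature


@dataclass(frozen=True)
class ClimateSpec:
    """Parameters of a synthetic site climate."""

    annual_mean_c: float = 10.0
    seasonal_amplitude_c: float = 11.0
    coldest_day_doy: int = 15
    diurnal_range_c: float = 8.0
    ar1_rho: float = 0.7
    noise_sd_c: float = 3.0
    latitude_deg: float = 43.0
    n_years: int = 3
    seed: int = 0
    start_year: int = 2000
    site_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd_c < 0 or self.seasonal_amplitude_c < 0:
            raise ValueError("noise_sd_c and seasonal_amplitude_c must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.diurnal_range_c < 0:
            raise ValueError("diurnal_range_c must be >= 0")


def _seasonal_mean(spec: ClimateSpec, doy: np.ndarray) -> np.ndarray:
    """Deterministic daily mean; minimum falls on ``coldest_day_doy``."""
    return spec.annual_mean_c - spec.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (doy - spec.coldest_day_doy) / 365.0
    )


def generate_weather(spec: ClimateSpec) -> SiteSeries:
    """Daily tmin/tmax covering ``n_years`` complete dormant seasons.

    The record runs 1 July ``start_year`` through 30 June
    ``start_year + n_years``; identical specs (same seed) produce identical
    series.
    """
    dates = pd.date_range(
        pd.Timestamp(spec.start_year, 7, 1),
        pd.Timestamp(spec.start_year + spec.n_years, 6, 30),
        freq="D",
    )
    doy = dates.dayofyear.to_numpy().astype(float)
    det = _seasonal_mean(spec, doy)
    rng = np.random.default_rng(spec.seed)
    innov_sd = spec.noise_sd_c * np.sqrt(1.0 - spec.ar1_rho ** 2)
    z = rng.normal(0.0, 1.0, len(dates)) * innov_sd
    eps = np.empty(len(dates))
    e = 0.0
    for i in range(len(dates)):
        e = spec.ar1_rho * e + z[i]
        eps[i] = e
    mean = det + eps
    half = spec.diurnal_range_c / 2.0
    frame = pd.DataFrame(
        {"tmin_c": mean - half, "tmax_c": mean + half}, index=dates
    )
    return SiteSeries(site_id=spec.site_id, latitude_deg=spec.latitude_deg,
                      frame=frame)


def expected_mdst(spec: ClimateSpec) -> float:
    """Noise-free MDST implied by the spec's sinusoid (non-leap calendar)."""
    window = pd.date_range("2001-11-01", "2002-04-30", freq="D")
    return float(_seasonal_mean(spec, window.dayofyear.to_numpy().astype(float)).mean())


def calibrate_spec_for_mdst(target_mdst_c: float,
                            template: ClimateSpec) -> ClimateSpec:
    """Shift the template's annual mean so the expected MDST hits the target.

    Closed form on the deterministic sinusoid: the seasonal term's mean over
    the 1 Nov-30 Apr window is independent of the annual mean.
    """
    seasonal_part = expected_mdst(replace(template, annual_mean_c=0.0))
    annual_mean = target_mdst_c - seasonal_part
    if abs(annual_mean) > 60.0:
        raise ValueError(
            f"target MDST {target_mdst_c} unreachable within physical bounds"
        )
    return replace(template, annual_mean_c=annual_mean)


@dataclass(frozen=True)
class SyntheticObservationSpec:
    """Noise model for synthetic phenology observations."""

    obs_noise_sd_days: float = 3.0
    convention: ObservationConvention = ObservationConvention.BBCH07_50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.obs_noise_sd_days < 0:
            raise ValueError("obs_noise_sd_days must be >= 0")


def generate_observations(
    predictions: list[BudbreakPrediction],
    spec: SyntheticObservationSpec,
) -> list[ObservationRecord]:
    """Noisy observations from model predictions (FAILED predictions are
    skipped); noise is Gaussian, rounded to whole days."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for pred in predictions:
        noise = rng.normal(0.0, spec.obs_noise_sd_days)
        if pred.failed:
            continue
        out.append(
            ObservationRecord(
                site_id=pred.site_id,
                cultivar=pred.cultivar,
                season_year=pred.season_year,
                observed_doy=int(pred.doy + round(noise)),
                convention=spec.convention,
            )
        )
    return out


def realized_mdst(series: SiteSeries) -> list[float]:
    """Per-season MDST of an emitted series (midpoint convention)."""
    return [
        mean_dormant_season_temperature(season)
        for season in split_seasons(series)
    ]
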