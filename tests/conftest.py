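import numpy as np
import pandas as pd
import pytest

from budfreeze import (
    ClimateSpec,
    accumulate_chill,
    calibrate_spec_for_mdst,
    generate_weather,
    split_seasons,
)
from budfreeze.weather import DormantSeason, season_hourly_temperatures


@pytest.fixture(scope="session")
def cold_spec():
    # MDST ~ 4 C: cold-climate site with abundant chill
    return calibrate_spec_for_mdst(
        4.0, ClimateSpec(n_years=3, seed=1234, site_id="cold")
    )


@pytest.fixture(scope="session")
def warm_spec():
    # MDST ~ 10.5 C: warm, chill-limited site
    return calibrate_spec_for_mdst(
        10.5, ClimateSpec(n_years=3, seed=987, site_id="warm")
    )


@pytest.fixture(scope="session")
def cold_series(cold_spec):
    return generate_weather(cold_spec)


@pytest.fixture(scope="session")
def warm_series(warm_spec):
    return generate_weather(warm_spec)


@pytest.fixture(scope="session")
def cold_season(cold_series):
    return split_seasons(cold_series)[0]


@pytest.fixture(scope="session")
def warm_season(warm_series):
    return split_seasons(warm_series)[0]


@pytest.fixture(scope="session")
def cold_chill(cold_season):
    return accumulate_chill(cold_season)


@pytest.fixture(scope="session")
def warm_chill(warm_season):
    return accumulate_chill(warm_season)


@pytest.fixture(scope="session")
def cold_hourly(cold_season):
    return season_hourly_temperatures(cold_season)


def inject_cold_snap(season: DormantSeason, date: str,
                     tmin_c: float = -35.0, n_days: int = 1) -> DormantSeason:
    """Copy of a season with a hard freeze inserted on ``date``."""
    frame = season.frame.copy()
    ts = pd.Timestamp(date)
    for k in range(n_days):
        day = ts + pd.Timedelta(days=k)
        frame.loc[day, "tmin_c"] = tmin_c
        frame.loc[day, "tmax_c"] = max(tmin_c + 5.0,
                                       frame.loc[day, "tmax_c"] - 15.0)
    return DormantSeason(
        site_id=season.site_id,
        latitude_deg=season.latitude_deg,
        season_year=season.season_year,
        frame=frame,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
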