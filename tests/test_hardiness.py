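import math

import numpy as np
import pytest

from budfreeze.chill import ChillSeries
from budfreeze.errors import AlignmentError, ParameterError
from budfreeze.hardiness import (
    SpringFloorConfig,
    acclimation_gain,
    deacclimation_loss,
    deacclimation_potential,
    integration_start_date,
    simulate_all_percentiles,
    simulate_hardiness,
)
from budfreeze.params import CULTIVARS, PERCENTILES, default_params, params_for


@pytest.fixture(scope="module")
def all_params():
    return [params_for(c, p) for c in CULTIVARS for p in PERCENTILES]


class TestDeacclimationPotential:
    def test_zero_chill_is_near_zero(self, all_params):
        for params in all_params:
            assert deacclimation_potential(params, 0.0) < 0.05

    def test_saturates_at_high_chill(self, all_params):
        for params in all_params:
            assert deacclimation_potential(params, 150.0) >= 0.95

    def test_monotone_in_chill(self, all_params):
        for params in all_params:
            assert deacclimation_potential(params, 50.0) < \
                deacclimation_potential(params, 100.0)

    def test_negative_chill_rejected(self, all_params):
        with pytest.raises(ValueError):
            deacclimation_potential(all_params[0], -1.0)


class TestAcclimationGain:
    def test_zero_at_maximum_hardiness_bound(self, all_params):
        for params in all_params:
            assert acclimation_gain(params, 40.0, -10.0,
                                    params.ch_max_c) == 0.0

    def test_colder_minimum_gains_at_least_as_much(self, all_params):
        for params in all_params:
            g_cold = acclimation_gain(params, 40.0, -10.0, -12.0)
            g_mild = acclimation_gain(params, 40.0, -2.0, -12.0)
            assert g_cold >= g_mild

    def test_more_chill_gains_at_most_as_much(self, all_params):
        for params in all_params:
            g20 = acclimation_gain(params, 20.0, -5.0, -12.0)
            g80 = acclimation_gain(params, 80.0, -5.0, -12.0)
            assert g20 >= g80

    def test_non_negative_over_random_sweep(self, all_params, rng):
        for _ in range(200):
            params = all_params[rng.integers(len(all_params))]
            gain = acclimation_gain(
                params,
                float(rng.uniform(0, 150)),
                float(rng.uniform(-30, 25)),
                float(rng.uniform(params.ch_max_c, 5.0)),
            )
            assert gain >= 0.0


class TestDeacclimationLoss:
    def test_zero_chill_gates_loss(self, all_params):
        for params in all_params:
            assert deacclimation_loss(params, 0.0, 10.0, 25.0) < 0.05

    def test_warmer_max_loses_at_least_as_much(self, all_params):
        for params in all_params:
            hot = deacclimation_loss(params, 150.0, 5.0, 25.0)
            mild = deacclimation_loss(params, 150.0, 5.0, 10.0)
            assert hot >= mild

    def test_hand_computed_fixture_day(self):
        # direct evaluation of the documented formulas for one input
        params = params_for("Riesling", 50)
        potential = 1.0 / (1.0 + math.exp(-0.15 * (100.0 - 80.0)))
        response = 0.5 * ((5.0 - 4.0) + (15.0 - 4.0))
        expected = potential * 0.30 * response
        assert deacclimation_loss(params, 100.0, 5.0, 15.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_tmin_above_tmax_rejected(self, all_params):
        with pytest.raises(ValueError):
            deacclimation_loss(all_params[0], 50.0, 10.0, 5.0)


class TestSimulateHardiness:
    def test_projected_crosses_into_positive(self, cold_season, cold_chill):
        ch50 = simulate_hardiness(params_for("Riesling", 50), cold_season,
                                  cold_chill, mode="projected")
        assert np.nanmax(ch50) > 10.0

    def test_bounded_capped_at_floor(self, cold_season, cold_chill):
        floor = SpringFloorConfig()
        ch50 = simulate_hardiness(params_for("Riesling", 50), cold_season,
                                  cold_chill, mode="bounded", floor=floor)
        assert np.nanmax(ch50) <= floor.floor50_c + 1e-12

    def test_never_below_max_hardiness_bound(self, cold_season, cold_chill):
        params = params_for("Concord", 90)
        ch = simulate_hardiness(params, cold_season, cold_chill)
        assert np.nanmin(ch) >= params.ch_max_c - 1e-12

    def test_nan_before_integration_start(self, cold_season, cold_chill):
        ch = simulate_hardiness(params_for("Riesling", 50), cold_season,
                                cold_chill)
        start = integration_start_date(cold_season)
        before = cold_season.dates < start
        assert np.isnan(ch[before]).all()
        assert not np.isnan(ch[~before]).any()

    def test_conservation_of_update(self, cold_season, cold_chill):
        # CH(d) - CH(d-1) == loss - gain wherever no clamp was active
        params = params_for("Riesling", 50)
        ch = simulate_hardiness(params, cold_season, cold_chill)
        cp = cold_chill.portions_cum
        tmin, tmax = cold_season.tmin_c, cold_season.tmax_c
        checked = 0
        for d in range(1, len(ch)):
            if np.isnan(ch[d - 1]) or np.isnan(ch[d]):
                continue
            if ch[d] <= params.ch_max_c + 1e-12:
                continue  # clamped day
            gain = acclimation_gain(params, cp[d], tmin[d], ch[d - 1])
            loss = deacclimation_loss(params, cp[d], tmin[d], tmax[d])
            assert ch[d] - ch[d - 1] == pytest.approx(loss - gain, abs=1e-12)
            checked += 1
        assert checked > 100

    def test_misaligned_chill_rejected(self, cold_season):
        shifted = cold_season.dates + np.timedelta64(1, "D")
        bad = ChillSeries(
            season_year=cold_season.season_year,
            dates=shifted,
            portions_cum=np.zeros(len(cold_season)),
        )
        with pytest.raises(AlignmentError):
            simulate_hardiness(params_for("Riesling", 50), cold_season, bad)

    def test_short_chill_rejected(self, cold_season):
        bad = ChillSeries(
            season_year=cold_season.season_year,
            dates=cold_season.dates[:100],
            portions_cum=np.zeros(100),
        )
        with pytest.raises(AlignmentError):
            simulate_hardiness(params_for("Riesling", 50), cold_season, bad)

    def test_projected_equals_bounded_until_floor_binds(self, cold_season,
                                                        cold_chill):
        params = params_for("Riesling", 50)
        floor = SpringFloorConfig()
        proj = simulate_hardiness(params, cold_season, cold_chill, "projected")
        bound = simulate_hardiness(params, cold_season, cold_chill, "bounded",
                                   floor)
        above = np.nonzero(~np.isnan(proj) & (proj > floor.floor50_c))[0]
        first_bind = above[0] if len(above) else len(proj)
        valid = ~np.isnan(proj[:first_bind])
        assert np.array_equal(proj[:first_bind][valid],
                              bound[:first_bind][valid])

    def test_u_shape_minimum_interior(self, cold_season, cold_chill):
        ch = simulate_hardiness(params_for("Riesling", 50), cold_season,
                                cold_chill)
        valid = np.nonzero(~np.isnan(ch))[0]
        arg = valid[np.nanargmin(ch[valid])]
        crossing = np.nonzero(~np.isnan(ch) & (ch >= 10.0))[0][0]
        assert valid[0] < arg < crossing

    def test_golden_trajectory_reproducible(self, cold_season, cold_chill):
        ch = simulate_hardiness(params_for("Riesling", 50), cold_season,
                                cold_chill)
        again = simulate_hardiness(params_for("Riesling", 50), cold_season,
                                   cold_chill)
        valid = ~np.isnan(ch)
        assert np.array_equal(ch[valid], again[valid])


class TestAllPercentiles:
    def test_daily_ordering(self, cold_season, cold_chill):
        traj = simulate_all_percentiles("Riesling", cold_season, cold_chill)
        valid = ~np.isnan(traj.ch50_c)
        assert (traj.ch10_c[valid] >= traj.ch50_c[valid]).all()
        assert (traj.ch50_c[valid] >= traj.ch90_c[valid]).all()

    def test_cultivars_differ_on_same_weather(self, cold_season, cold_chill):
        a = simulate_all_percentiles("Riesling", cold_season, cold_chill)
        b = simulate_all_percentiles("Cabernet-Sauvignon", cold_season,
                                     cold_chill)
        valid = ~np.isnan(a.ch50_c)
        assert not np.allclose(a.ch50_c[valid], b.ch50_c[valid])

    def test_concord_hardier_than_cabernet_midwinter(self, cold_season,
                                                     cold_chill):
        con = simulate_all_percentiles("Concord", cold_season, cold_chill)
        cab = simulate_all_percentiles("Cabernet-Sauvignon", cold_season,
                                       cold_chill)
        assert np.nanmin(con.ch50_c) < np.nanmin(cab.ch50_c)

    def test_unknown_cultivar_rejected(self, cold_season, cold_chill):
        with pytest.raises(ParameterError):
            simulate_all_percentiles("Merlot", cold_season, cold_chill)


class TestMonotoneResponseSuite:
    """Randomized sweeps of the six documented monotonicity statements."""

    def test_all_parameter_sets(self, all_params, rng):
        for params in all_params:
            cp = np.sort(rng.uniform(0, 150, 10))
            tmins = np.sort(rng.uniform(-25, 15, 10))
            ch_prev = float(rng.uniform(params.ch_max_c, 0.0))
            # (1i) more chill -> acclimation needs colder temps (gain falls)
            gains = [acclimation_gain(params, c, -5.0, ch_prev) for c in cp]
            assert (np.diff(gains) <= 1e-12).all()
            # (1ii) colder minimum -> more gain
            gains = [acclimation_gain(params, 40.0, t, ch_prev) for t in tmins]
            assert (np.diff(gains) <= 1e-12).all()
            # (1iii) hardier previous day -> less gain
            chs = np.sort(rng.uniform(params.ch_max_c, 0.0, 10))
            gains = [acclimation_gain(params, 40.0, -5.0, c) for c in chs]
            assert (np.diff(gains) >= -1e-12).all()
            # (2i) effective loss = potential x rate (gate at zero chill)
            assert deacclimation_loss(params, 0.0, 10.0, 20.0) <= \
                deacclimation_potential(params, 0.0) * params.dea_rate * 16.0
            # (2ii) warmer -> more loss
            losses = [deacclimation_loss(params, 100.0, t, t + 10.0)
                      for t in tmins]
            assert (np.diff(losses) >= -1e-12).all()
            # (2iii) more chill -> more loss
            losses = [deacclimation_loss(params, c, 5.0, 15.0) for c in cp]
            assert (np.diff(losses) >= -1e-12).all()


class TestSpringFloorConfig:
    def test_defaults_ordered(self):
        floor = SpringFloorConfig()
        assert floor.floor10_c >= floor.floor50_c >= floor.floor90_c

    def test_unordered_rejected(self):
        with pytest.raises(ParameterError):
            SpringFloorConfig(floor10_c=-5.0, floor50_c=-1.0, floor90_c=-2.0)


def test_parameter_table_complete():
    table = default_params()
    assert len(table) == 9
    for (cultivar, pct), params in table.items():
        assert params.ch_max_c < 0
        assert params.cultivar == cultivar
        assert params.percentile == pct
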