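"""Crop growth and the hourly limited-transpiration mechanism."""

import numpy as np
import pandas as pd
import pytest

from sorglt import cropmodel as cm
from sorglt import weathergen as wg
from sorglt.config import CROP


class TestThermalTime:
    @pytest.mark.parametrize("tmax,tmin,expected", [
        (11.0, 11.0, 0.0),            # at base
        (30.0, 20.0, 14.0),           # linear segment: mean 25 - 11
        (42.0, 42.0, 0.0),            # at ceiling
        (30.0, 30.0, 19.0),           # at optimum: Topt - Tbase
    ])
    def test_broken_stick(self, tmax, tmin, expected):
        assert cm.daily_thermal_time(tmax, tmin) == pytest.approx(expected)

    def test_declines_above_optimum(self):
        assert cm.daily_thermal_time(38, 32) < cm.daily_thermal_time(32, 28)


class TestPhenology:
    def test_anthesis_day_50_at_constant_14(self, constant_weather):
        """Targets summing to 700 degC d to flowering, 14 degC d per day."""
        phase_tt = (1.0, 49.0, 100.0, 150.0, 250.0, 150.0, 80.0, 500.0, 30.0)
        assert sum(phase_tt[:6]) == 700.0
        cv = cm.make_cultivar("short", phase_tt=phase_tt)
        state = cm.PhenologyState(cv)
        day = 0
        while not state.flowering:
            cm.advance_phenology(state, 14.0, 12.0)
            day += 1
        assert day == 50

    def test_zero_slope_ignores_daylength(self):
        cv = cm.make_cultivar("short")
        a, b = cm.PhenologyState(cv), cm.PhenologyState(cv)
        for _ in range(80):
            cm.advance_phenology(a, 14.0, 11.0)
            cm.advance_phenology(b, 14.0, 15.0)
        assert a.phase == b.phase and a.cum_tt == b.cum_tt

    def test_positive_slope_delays_floral_initiation(self):
        cv = cm.make_cultivar("short", photoperiod_slope=20.0)
        short_day, long_day = cm.PhenologyState(cv), cm.PhenologyState(cv)
        for _ in range(40):
            cm.advance_phenology(short_day, 14.0, 12.0)
            cm.advance_phenology(long_day, 14.0, 15.0)
        assert long_day.phase <= short_day.phase

    def test_short_season_flowers_in_fewer_degree_days(self):
        tt = {m: cm.make_cultivar(m).tt_to("flowering")
              for m in ("short", "medium", "full")}
        assert tt["short"] < tt["medium"] < tt["full"]


class TestLeafArea:
    def _state_at(self, cv, cum_tt):
        s = cm.PhenologyState(cv, phase=2, cum_tt=cum_tt)
        return s

    def test_logistic_midpoint(self):
        cv = cm.make_cultivar("short")
        lai = cm.leaf_area(self._state_at(cv, cv.tpla_inflection), cv, density=1.0)
        assert lai == pytest.approx(cv.tplamax * 1.3 / 2)

    def test_lai_proportional_to_density_before_senescence(self):
        cv = cm.make_cultivar("short")
        s = self._state_at(cv, 600.0)
        assert cm.leaf_area(s, cv, 20.0) == pytest.approx(
            2 * cm.leaf_area(s, cv, 10.0))

    def test_full_season_peak_exceeds_short(self):
        big = cm.make_cultivar("full")
        small = cm.make_cultivar("short")
        lai_big = cm.leaf_area(self._state_at(big, 2000), big, 10.0)
        lai_small = cm.leaf_area(self._state_at(small, 2000), small, 10.0)
        assert lai_big > lai_small

    def test_zero_before_emergence(self):
        cv = cm.make_cultivar("short")
        assert cm.leaf_area(cm.PhenologyState(cv, phase=1, cum_tt=30), cv, 10) == 0.0


class TestLightLimitedBiomass:
    def test_values(self):
        assert cm.light_limited_biomass(20, 0) == 0.0
        assert cm.light_limited_biomass(20, 2, rue=1.25, k=0.5) == pytest.approx(
            1.25 * 20 * (1 - np.exp(-1.0)))
        assert cm.light_limited_biomass(20, 1e6, rue=1.25) == pytest.approx(25.0)


class TestHourlyDownscaling:
    def test_flat_day(self):
        assert np.allclose(cm.hourly_temperature(20.0, 20.0), 20.0)

    def test_extremes_hit_exactly(self):
        t = cm.hourly_temperature(34.0, 18.0)
        assert t.max() == pytest.approx(34.0) and t.min() == pytest.approx(18.0)

    def test_afternoon_warmer_than_night(self):
        t = cm.hourly_temperature(30.0, 15.0)
        assert t[14] > t[4]

    def test_vpd_tetens_value(self):
        v = cm.hourly_vpd(30.0, 15.0)
        assert cm.svp(30.0) == pytest.approx(4.243, abs=2e-3)
        assert cm.svp(15.0) == pytest.approx(1.706, abs=2e-3)
        assert v.max() == pytest.approx(4.243 - 1.706, abs=5e-3)

    def test_vpd_zero_at_dewpoint_hour(self):
        v = cm.hourly_vpd(30.0, 15.0)
        assert v.min() == pytest.approx(0.0)

    def test_vpd_peaks_at_hottest_hour(self):
        v = cm.hourly_vpd(33.0, 17.0)
        assert int(np.argmax(v)) == 14

    def test_radiation_shares_sum_to_one_in_daylight(self):
        s = cm.radiation_shares(180)
        assert s.sum() == pytest.approx(1.0)
        assert s[0] == 0.0 and s[23] == 0.0  # night


class TestDemandAndCap:
    def test_hand_demand(self):
        shares = np.zeros(24)
        shares[12] = 1.0
        vpd = np.full(24, 2.0)
        d = cm.hourly_demand(20.0, shares, vpd, te_coeff=9.0)
        assert d[12] == pytest.approx(20 * 2 / 9)
        assert d.sum() == pytest.approx(4.444, abs=1e-3)

    def test_zero_vpd_zero_demand(self):
        d = cm.hourly_demand(20.0, cm.radiation_shares(180), np.zeros(24))
        assert d.sum() == 0.0

    def test_cap_clips_elementwise(self):
        demand = np.zeros(24)
        demand[10:14] = [0.2, 0.5, 1.2, 0.8]
        capped = cm.apply_lt_cap(demand, 0.9)
        assert capped[10:14].tolist() == [0.2, 0.5, 0.9, 0.8]
        assert capped.sum() == pytest.approx(2.4)
        assert demand.sum() == pytest.approx(2.7)

    def test_loose_cap_is_identity(self):
        demand = np.linspace(0, 0.8, 24)
        assert np.array_equal(cm.apply_lt_cap(demand, 0.9), demand)
        assert cm.apply_lt_cap(demand, None) is demand

    def test_capped_total_monotone_in_cap(self):
        demand = np.linspace(0, 1.5, 24)
        totals = [cm.apply_lt_cap(demand, c).sum() for c in (0.2, 0.5, 0.9)]
        assert totals == sorted(totals)


class TestWaterLimitedGrowth:
    def test_ample_supply_transpires_full_demand(self):
        vpd = np.full(24, 2.0)
        demand = np.full(24, 0.1)
        b, tr, sd = cm.water_limited_growth(demand, 100.0, vpd)
        assert sd == 1.0 and tr == pytest.approx(2.4)

    def test_stress_ratio(self):
        vpd = np.full(24, 2.0)
        demand = np.full(24, 4.44 / 24)
        _, tr, sd = cm.water_limited_growth(demand, 2.1, vpd)
        assert sd == pytest.approx(2.1 / 4.44, abs=1e-3)
        assert tr == pytest.approx(2.1)

    def test_zero_demand_day_grows_light_limited(self):
        light = np.full(24, 0.5)
        b, tr, sd = cm.water_limited_growth(
            np.zeros(24), 5.0, np.zeros(24), light_hourly=light)
        assert sd == 1.0 and tr == 0.0 and b == pytest.approx(12.0)

    def test_biomass_never_exceeds_light_limited(self):
        vpd = cm.hourly_vpd(35.0, 18.0)
        shares = cm.radiation_shares(190)
        light = 25.0 * shares
        demand = cm.hourly_demand(25.0, shares, vpd)
        b, _, _ = cm.water_limited_growth(demand, 100.0, vpd, light_hourly=light)
        assert b <= 25.0 + 1e-9


class TestGrain:
    def test_grain_number_division(self):
        assert cm.grain_number(2.5, 0.00099) == pytest.approx(2525.25, abs=0.01)

    def test_zero_growth_zero_grains(self):
        assert cm.grain_number(0.0, 0.00099) == 0.0

    def test_moisture_conversion(self):
        assert cm.reported_yield(5.0) == pytest.approx(5.714, abs=1e-3)

    def test_grain_yield_raises_before_grain_fill(self, belt_soil, ed_weather):
        res = cm.run_season(ed_weather, belt_soil, cm.make_cultivar("short"),
                            cm.Management(sowing=300))  # sown far too late
        with pytest.raises(ValueError, match="grain fill"):
            cm.grain_yield(res)


class TestRunSeason:
    def test_daily_records_and_bounds(self, ed_season):
        d = ed_season.daily
        assert ((d.watersd >= 0) & (d.watersd <= 1)).all()
        assert (d.lai >= 0).all() and (d.biomass >= 0).all()
        assert d.cum_tt.is_monotonic_increasing
        assert ed_season.yield_mg_ha >= 0

    def test_hourly_sums_match_daily_transpiration(self, ed_season):
        np.testing.assert_allclose(
            ed_season.hourly_transp.sum(axis=1),
            ed_season.daily.transp.to_numpy(), atol=1e-9)

    def test_reported_yield_conversion(self, ed_season):
        assert ed_season.yield_mg_ha == pytest.approx(
            ed_season.dry_yield / 0.875)

    def test_water_balance_closes(self, ed_season):
        assert ed_season.ledger.max_residual() < 1e-6

    def test_transpiration_bounded_by_water_in(self, ed_season):
        f = ed_season.ledger.frame
        initial_available = 0.6 * 0.12 * 1500  # 60% of sandy-loam PAWC
        assert ed_season.total_transpiration <= (
            initial_available + f.infiltration.sum() + 1e-6)

    def test_lt_cap_never_exceeded(self, belt_soil, ed_weather):
        res = cm.run_season(ed_weather, belt_soil,
                            cm.make_cultivar("short", 0.5), cm.Management())
        assert (res.hourly_transp <= 0.5 + 1e-12).all()

    def test_lt_identical_when_cap_never_binds(self, belt_soil, constant_weather):
        """A cap above the demand peak must reproduce non-LT bit for bit."""
        base = cm.run_season(constant_weather, belt_soil,
                             cm.make_cultivar("short", None), cm.Management())
        assert base.hourly_transp.max() < 0.9  # mild weather: cap inactive
        lt = cm.run_season(constant_weather, belt_soil,
                           cm.make_cultivar("short", 0.9), cm.Management())
        pd.testing.assert_frame_equal(base.daily, lt.daily)
        assert base.yield_mg_ha == lt.yield_mg_ha

    def test_lt_saves_water_by_flowering(self, belt_soil, ed_weather):
        base = cm.run_season(ed_weather, belt_soil,
                             cm.make_cultivar("short", None), cm.Management())
        lt = cm.run_season(ed_weather, belt_soil,
                           cm.make_cultivar("short", 0.2), cm.Management())
        assert lt.transp_at_flowering <= base.transp_at_flowering + 1e-9
        assert lt.pasw_at_flowering >= base.pasw_at_flowering - 1e-9

    def test_zero_rain_low_moisture_season_fails(self, belt_soil):
        w = wg.generate_season("ED", 0, seed=1).copy()
        w["rain"] = 0.0
        res = cm.run_season(w, belt_soil, cm.make_cultivar("short"),
                            cm.Management(initial_fraction=0.2))
        assert res.failed
        assert np.isnan(res.yield_mg_ha)

    def test_weather_too_short_rejected(self, belt_soil, ww_weather):
        with pytest.raises(ValueError, match="sowing"):
            cm.run_season(ww_weather.iloc[:100], belt_soil,
                          cm.make_cultivar("short"), cm.Management())


class TestCultivarValidation:
    def test_cap_outside_trait_range_rejected(self):
        with pytest.raises(ValueError):
            cm.make_cultivar("short", 1.5)

    def test_leaf_numbers(self):
        assert cm.make_cultivar("short").leaf_number == 15
        assert cm.make_cultivar("medium").leaf_number == 17
        assert cm.make_cultivar("full").leaf_number == 19
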