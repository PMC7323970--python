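"""Predictor derivation: window arithmetic, CV, diurnal range, assembly."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

import agrisuit as ag
from agrisuit.variables import (
    GROWING_SEASON, MAR_SEP, SOWING_MONTH, DateWindow,
    assemble_variables, diurnal_range, rain_cv, window_rain_sum, window_temp_mean,
)
from conftest import make_region, make_weather

SOUTH_GS_DAYS = 122   # 1 Mar - 30 Jun, non-leap: 31+30+31+30
NORTH_GS_DAYS = 130   # 24 May - 30 Sep: 8+30+31+31+30


class TestWindowRainSum:
    def test_constant_rain_south_growing_window(self):
        w = make_weather(years=2, precip=1.0)   # 2006-2007, both non-leap
        out = window_rain_sum(w, GROWING_SEASON[0])
        assert np.allclose(out, SOUTH_GS_DAYS)

    def test_window_day_counts_by_calendar_enumeration(self):
        import pandas as pd
        idx = pd.date_range("2006-01-01", "2006-12-31", freq="D")
        assert int(GROWING_SEASON[0].day_mask(idx).sum()) == SOUTH_GS_DAYS
        assert int(GROWING_SEASON[1].day_mask(idx).sum()) == NORTH_GS_DAYS
        assert int(SOWING_MONTH[1].day_mask(idx).sum()) == 38
        assert int(SOWING_MONTH[0].day_mask(idx).sum()) == 61
        assert int(MAR_SEP.day_mask(idx).sum()) == 214

    def test_zero_precipitation(self):
        w = make_weather(precip=0.0)
        assert np.allclose(window_rain_sum(w, MAR_SEP), 0.0)

    def test_north_south_differ_by_day_count_ratio(self):
        w = make_weather(ny=2, nx=2, years=1, precip=1.0)
        zone = xr.zeros_like(w["precip"].isel(time=0), dtype=np.int8)
        zone[0, :] = 1   # first row north
        out = window_rain_sum(w, GROWING_SEASON, zone)
        assert np.allclose(out[0, :], NORTH_GS_DAYS)
        assert np.allclose(out[1, :], SOUTH_GS_DAYS)
        assert np.allclose(out[0, 0] / out[1, 0], NORTH_GS_DAYS / SOUTH_GS_DAYS)

    def test_window_outside_span_rejected(self):
        w = make_weather(years=1)
        sub = w.isel(time=slice(0, 40))   # January-February only
        with pytest.raises(ValueError, match="outside"):
            window_rain_sum(sub, MAR_SEP)

    def test_zone_window_selection(self):
        # rain only in July-September: inside the north window, outside the south one
        idx = make_weather(years=1).indexes["time"]
        daily = np.where(idx.month >= 7, 2.0, 0.0)
        w = make_weather(ny=2, nx=2, years=1, precip=daily)
        zone = xr.zeros_like(w["precip"].isel(time=0), dtype=np.int8)
        zone[0, :] = 1
        out = window_rain_sum(w, GROWING_SEASON, zone)
        assert (out.to_numpy()[0, :] > 0).all()
        assert np.allclose(out.to_numpy()[1, :], 0.0)


class TestRainCV:
    def test_identical_monthly_sums_zero_cv(self):
        # equal daily rate gives unequal monthly sums (month lengths), so
        # build rates inversely proportional to month length
        idx = make_weather(years=1).indexes["time"]
        daily = 120.0 / idx.days_in_month.to_numpy()
        w = make_weather(years=1, precip=daily)
        assert np.allclose(rain_cv(w), 0.0, atol=1e-6)

    def test_hand_computed_cv(self):
        # monthly sums Mar-Aug = 100 each, Sep = 240, one year
        idx = make_weather(years=1).indexes["time"]
        target = np.where(idx.month == 9, 240.0, 100.0)
        daily = target / idx.days_in_month.to_numpy()
        w = make_weather(years=1, precip=daily)
        sums = np.array([100.0] * 6 + [240.0])
        expect = 100.0 * sums.std(ddof=1) / sums.mean()
        assert np.allclose(rain_cv(w), expect)
        expect_pop = 100.0 * sums.std(ddof=0) / sums.mean()
        assert np.allclose(rain_cv(w, ddof=0), expect_pop)

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        idx = make_weather(years=1).indexes["time"]
        rng = np.random.default_rng(0)
        daily = rng.gamma(2.0, 2.0, size=len(idx))
        w = make_weather(ny=1, nx=1, years=1, precip=daily)
        w2 = w.copy()
        w2["precip"] = w["precip"] * c
        np.testing.assert_allclose(rain_cv(w2), rain_cv(w), rtol=1e-9)

    def test_zero_rain_pixel_flagged_nan(self):
        w = make_weather(precip=0.0)
        with pytest.warns(UserWarning, match="undefined"):
            out = rain_cv(w)
        assert np.isnan(out).all()


class TestDiurnalRange:
    def test_zero_range(self):
        w = make_weather(tmax=25.0, tmin=25.0)
        assert np.allclose(diurnal_range(w), 0.0)

    def test_constant_range_9p9(self):
        w = make_weather(tmax=29.9, tmin=20.0)
        assert np.allclose(diurnal_range(w), 9.9)

    def test_alternating_ranges_average(self):
        idx = make_weather(years=1).indexes["time"]
        rng_day = np.where(np.arange(len(idx)) % 2 == 0, 8.0, 12.0)
        w = make_weather(years=1, tmax=20.0 + rng_day, tmin=20.0)
        got = float(diurnal_range(w).isel(lat=0, lon=0))
        assert got == pytest.approx(10.0, abs=0.05)   # 214-day window, near-even split

    def test_tmax_below_tmin_rejected(self):
        w = make_weather(tmax=10.0, tmin=20.0)
        with pytest.raises(ValueError, match="tmax < tmin"):
            diurnal_range(w)

    def test_invariant_under_common_shift(self):
        w = make_weather(tmax=30.0, tmin=22.0)
        w2 = w.copy()
        w2["tmax"] = w["tmax"] + 3.3
        w2["tmin"] = w["tmin"] + 3.3
        np.testing.assert_allclose(diurnal_range(w2), diurnal_range(w), rtol=1e-6)


class TestWindowTempMean:
    def test_constant_temperature(self):
        w = make_weather(tmax=24.5, tmin=24.5)
        for window in (MAR_SEP, GROWING_SEASON[0], GROWING_SEASON[1]):
            assert np.allclose(window_temp_mean(w, window), 24.5)

    def test_linear_ramp_midpoint(self):
        idx = make_weather(years=1).indexes["time"]
        ramp = np.linspace(10.0, 30.0, len(idx))
        w = make_weather(years=1, tmax=ramp, tmin=ramp)
        sel = MAR_SEP.day_mask(idx)
        expect = ramp[sel].mean()          # mean of an arithmetic sequence = midpoint
        assert expect == pytest.approx((ramp[sel][0] + ramp[sel][-1]) / 2)
        assert np.allclose(window_temp_mean(w, MAR_SEP), expect)

    def test_translation_equivariance(self):
        w = make_weather(tmax=30.0, tmin=20.0)
        w2 = w.copy()
        w2["tmax"] = w["tmax"] + 2.2
        w2["tmin"] = w["tmin"] + 2.2
        np.testing.assert_allclose(window_temp_mean(w2, MAR_SEP),
                                   window_temp_mean(w, MAR_SEP) + 2.2, rtol=1e-9)


class TestAssemble:
    def test_composition_matches_single_operations(self):
        w = make_weather(ny=2, nx=3, years=2, precip=2.0, tmax=30.0, tmin=21.0)
        r = make_region(ny=2, nx=3, zone=0)
        out = assemble_variables(w, r)
        zone = r["zone"]
        np.testing.assert_allclose(out["rain_growing_season"],
                                   window_rain_sum(w, GROWING_SEASON, zone))
        np.testing.assert_allclose(out["rain_mar_sep"], window_rain_sum(w, MAR_SEP))
        np.testing.assert_allclose(out["dtr_mar_sep"], diurnal_range(w))
        np.testing.assert_allclose(out["tmean_mar_sep"], window_temp_mean(w, MAR_SEP))
        np.testing.assert_allclose(out["soil_organic_carbon"], 25.0)

    def test_growing_season_subwindow_of_mar_sep(self, varset20):
        gs = varset20["rain_growing_season"].to_numpy()
        ms = varset20["rain_mar_sep"].to_numpy()
        ok = np.isfinite(gs)
        assert (gs[ok] <= ms[ok] + 1e-6).all()

    def test_masked_pixels_nan_everywhere(self):
        w = make_weather(ny=2, nx=2)
        r = make_region(ny=2, nx=2)
        r["crop_mask"][0, 0] = False
        out = assemble_variables(w, r)
        for v in out.data_vars:
            assert np.isnan(out[v].to_numpy()[0, 0])
            assert np.isfinite(out[v].to_numpy()[1, 1])

    def test_purity(self, weather20, region20):
        a = assemble_variables(weather20, region20)
        b = assemble_variables(weather20, region20)
        xr.testing.assert_identical(a, b)

    def test_grid_mismatch_rejected(self):
        w = make_weather(ny=2, nx=2)
        r = make_region(ny=3, nx=3)
        with pytest.raises(ValueError, match="grid"):
            assemble_variables(w, r)

    def test_rainfall_fields_nonnegative(self, varset20):
        for v in ("rain_growing_season", "rain_mar_sep", "rain_sowing_month",
                  "rain_cv", "dtr_mar_sep"):
            assert np.nanmin(varset20[v].to_numpy()) >= 0.0

    def test_date_window_validation(self):
        with pytest.raises(ValueError, match="start after end"):
            DateWindow(9, 30, 3, 1)
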