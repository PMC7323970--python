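"""Derivation of the eight biophysical suitability predictors.

From daily precipitation and min/max temperature, a north/south zone map and
a topsoil organic-carbon grid, this module computes the predictor set used
for four-class suitability modelling:

===========================  =====================================================
``rain_growing_season``      rainfall sum in the zone's main growing season (mm):
                             24 May-30 Sep in the north, 1 Mar-30 Jun in the south
``rain_mar_sep``             rainfall sum 1 Mar-30 Sep, both zones (mm)
``rain_sowing_month``        rainfall sum in the sowing window (mm):
                             24 May-30 Jun north, 1 Mar-30 Apr south
``rain_cv``                  coefficient of variation of Mar-Sep monthly rainfall
                             sums (%), pooled over years by default
``dtr_mar_sep``              mean diurnal temperature range 1 Mar-30 Sep (degC)
``tmean_growing_season``     mean daily temperature in the growing season (degC)
``tmean_mar_sep``            mean daily temperature 1 Mar-30 Sep (degC)
``soil_organic_carbon``      topsoil organic carbon (t/ha), taken as given
===========================  =====================================================

Windows are defined by calendar month/day and resolved per year; annual
window statistics are averaged over all years present.  Daily mean
temperature is (tmax + tmin) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DateWindow",
    "GROWING_SEASON",
    "MAR_SEP",
    "SOWING_MONTH",
    "VARIABLE_NAMES",
    "window_rain_sum",
    "rain_cv",
    "diurnal_range",
    "window_temp_mean",
    "assemble_variables",
]

ZONE_SOUTH, ZONE_NORTH = 0, 1


@dataclass(frozen=True)
class DateWindow:
    """A within-year calendar window [start, end], inclusive on both ends."""

    start_month: int
    start_day: int
    end_month: int
    end_day: int

    def __post_init__(self) -> None:
        if (self.start_month, self.start_day) > (self.end_month, self.end_day):
            raise ValueError(f"window start after end: {self}")

    def day_mask(self, index: pd.DatetimeIndex) -> np.ndarray:
        md = index.month * 100 + index.day
        return (md >= self.start_month * 100 + self.start_day) & \
               (md <= self.end_month * 100 + self.end_day)

    def n_days(self, year: int) -> int:
        """Number of calendar days in the window for a given year."""
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        return int(self.day_mask(idx).sum())


#: zone-specific windows, keyed by zone code (0=south, 1=north)
GROWING_SEASON = {ZONE_NORTH: DateWindow(5, 24, 9, 30), ZONE_SOUTH: DateWindow(3, 1, 6, 30)}
SOWING_MONTH = {ZONE_NORTH: DateWindow(5, 24, 6, 30), ZONE_SOUTH: DateWindow(3, 1, 4, 30)}
MAR_SEP = DateWindow(3, 1, 9, 30)

VARIABLE_NAMES = (
    "rain_growing_season", "rain_mar_sep", "rain_sowing_month", "rain_cv",
    "dtr_mar_sep", "tmean_growing_season", "tmean_mar_sep", "soil_organic_carbon",
)


def _time_index(weather: xr.Dataset) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(weather["time"].to_numpy())


def _check_window(weather: xr.Dataset, window: DateWindow) -> None:
    idx = _time_index(weather)
    if not window.day_mask(idx).any():
        raise ValueError(f"window {window} lies outside the data's date span")


def _annual_window_stat(da: xr.DataArray, window: DateWindow, how: str) -> xr.DataArray:
    """Per-year within-window sum or mean, then multi-year mean, per pixel."""
    idx = pd.DatetimeIndex(da["time"].to_numpy())
    sub = da.isel(time=window.day_mask(idx))
    grouped = sub.groupby("time.year")
    annual = grouped.sum("time") if how == "sum" else grouped.mean("time")
    return annual.mean("year")


def _per_zone(weather: xr.Dataset, da: xr.DataArray,
              windows: dict[int, DateWindow] | DateWindow, zone: xr.DataArray | None,
              how: str) -> xr.DataArray:
    if isinstance(windows, DateWindow):
        _check_window(weather, windows)
        return _annual_window_stat(da, windows, how)
    if zone is None:
        raise ValueError("zone map required for zone-specific windows")
    out = None
    zvals = zone.to_numpy()
    for zcode, window in windows.items():
        _check_window(weather, window)
        stat = _annual_window_stat(da, window, how)
        out = stat.where(zvals == zcode, out) if out is not None \
            else stat.where(zvals == zcode)
    return out


def window_rain_sum(weather: xr.Dataset,
                    window: dict[int, DateWindow] | DateWindow,
                    zone: xr.DataArray | None = None) -> xr.DataArray:
    """Multi-year mean of the annual within-window precipitation sum (mm).

    ``window`` is either a single :class:`DateWindow` applied everywhere, or
    a ``{zone code: DateWindow}`` mapping with a ``zone`` grid selecting the
    window per pixel.
    """
    return _per_zone(weather, weather["precip"], window, zone, "sum")


def window_temp_mean(weather: xr.Dataset,
                     window: dict[int, DateWindow] | DateWindow,
                     zone: xr.DataArray | None = None) -> xr.DataArray:
    """Multi-year mean of daily mean temperature ((tmax+tmin)/2) in a window."""
    tmean = (weather["tmax"] + weather["tmin"]) / 2.0
    tmean = tmean.rename("tmean").assign_coords(time=weather["time"])
    return _per_zone(weather, tmean, window, zone, "mean")


def rain_cv(weather: xr.Dataset, *, ddof: int = 1, pooled: bool = True) -> xr.DataArray:
    """Coefficient of variation of Mar-Sep monthly rainfall sums, percent.

    Monthly sums are formed per pixel for each March-September month of each
    year.  With ``pooled`` (default) the sd and mean pool all year x month
    sums (7 x n_years values); otherwise the CV is computed per year and
    averaged.  ``ddof=1`` gives the sample standard deviation; 0 population.
    Pixels with zero mean monthly rainfall are undefined and returned as NaN.
    """
    idx = _time_index(weather)
    sub = weather["precip"].isel(time=(idx.month >= 3) & (idx.month <= 9))
    monthly = sub.resample(time="MS").sum()
    # resampling re-introduces empty Oct-Feb bins between years; drop them
    monthly = monthly.isel(time=monthly["time"].dt.month.isin(range(3, 10)).to_numpy())

    def _cv(arr: np.ndarray) -> np.ndarray:   # arr: (n_months, ny, nx)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(mean > 0, 100.0 * sd / mean, np.nan)
        return out

    if pooled:
        cv = _cv(monthly.to_numpy())
    else:
        years = monthly["time"].dt.year.to_numpy()
        per_year = [_cv(monthly.to_numpy()[years == y]) for y in np.unique(years)]
        cv = np.nanmean(np.stack(per_year), axis=0)
    if np.isnan(cv).any():
        warnings.warn("rain_cv undefined (zero mean monthly rainfall) at "
                      f"{int(np.isnan(cv).sum())} pixels; returned NaN", stacklevel=2)
    return xr.DataArray(cv, coords={"lat": weather["lat"], "lon": weather["lon"]},
                        dims=("lat", "lon"), name="rain_cv", attrs={"units": "%"})


def diurnal_range(weather: xr.Dataset, window: DateWindow = MAR_SEP) -> xr.DataArray:
    """Mean diurnal temperature range (tmax - tmin) over the window (degC)."""
    dtr = weather["tmax"] - weather["tmin"]
    if float(dtr.min()) < 0:
        raise ValueError("input has days with tmax < tmin")
    _check_window(weather, window)
    return _annual_window_stat(dtr.assign_coords(time=weather["time"]), window, "mean")


def assemble_variables(weather: xr.Dataset, region: xr.Dataset, *,
                       cv_ddof: int = 1, cv_pooled: bool = True) -> xr.Dataset:
    """Compute the full eight-variable predictor set on the region's grid.

    Masked-out pixels carry NaN in every field; soil organic carbon is copied
    from the region unchanged (within the mask).
    """
    if not (np.array_equal(weather["lat"], region["lat"]) and
            np.array_equal(weather["lon"], region["lon"])):
        raise ValueError("weather and region grids do not match")
    zone = region["zone"]
    fields = {
        "rain_growing_season": window_rain_sum(weather, GROWING_SEASON, zone),
        "rain_mar_sep": window_rain_sum(weather, MAR_SEP),
        "rain_sowing_month": window_rain_sum(weather, SOWING_MONTH, zone),
        "rain_cv": rain_cv(weather, ddof=cv_ddof, pooled=cv_pooled),
        "dtr_mar_sep": diurnal_range(weather),
        "tmean_growing_season": window_temp_mean(weather, GROWING_SEASON, zone),
        "tmean_mar_sep": window_temp_mean(weather, MAR_SEP),
        "soil_organic_carbon": region["soil_carbon"].astype(np.float64),
    }
    mask = region["crop_mask"]
    out = xr.Dataset({k: v.where(mask).rename(k) for k, v in fields.items()},
                     coords={"lat": region["lat"], "lon": region["lon"]})
    for k in ("rain_growing_season", "rain_mar_sep", "rain_sowing_month"):
        out[k].attrs["units"] = "mm"
    for k in ("dtr_mar_sep", "tmean_growing_season", "tmean_mar_sep"):
        out[k].attrs["units"] = "degC"
    out["rain_cv"].attrs["units"] = "%"
    out["soil_organic_carbon"].attrs["units"] = "t/ha"
    return out
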