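"""Seeded synthetic stand-ins for the study inputs.

Emulates the structure of the data streams behind a national crop-suitability
analysis: daily gridded precipitation with a unimodal (north) versus bimodal
(south) seasonal cycle, daily min/max temperature with a realistic diurnal
range, a cropland mask, a north/south climatic zone split, a district
partition of the masked pixels, a topsoil organic-carbon grid, and multi-year
district yield tables whose spatial signal is a known monotone function of a
chosen agro-climatic driver.  Because the yield-generating truth is known,
every downstream stage (classing, model fitting, importance) can be tested
as a parameter-recovery problem.

All randomness descends from one root seed through named substreams, so
adding or re-ordering components never perturbs another component's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = [
    "GridSpec",
    "ZoneClimate",
    "TruthSpec",
    "NORTH_DEFAULT",
    "SOUTH_DEFAULT",
    "generate_weather",
    "generate_region",
    "generate_yields",
]


# --------------------------------------------------------------------------
# grid and parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid; 0.05 degree default spacing."""

    ny: int
    nx: int
    lat_min: float = 4.5
    lon_min: float = -3.5
    res: float = 0.05

    def __post_init__(self) -> None:
        if self.ny <= 0 or self.nx <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.ny}x{self.nx}")
        if self.res <= 0:
            raise ValueError("grid resolution must be positive")

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.res * np.arange(self.ny)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.res * np.arange(self.nx)

    @property
    def mid_lat(self) -> float:
        return float(self.lat_min + self.res * (self.ny - 1) / 2.0)


@dataclass(frozen=True)
class ZoneClimate:
    """Seasonal climate parameters for one zone (north or south).

    Rainfall follows a deterministic seasonal mean rate ``base +
    amplitude * kernel(doy)`` where the kernel is a sum of Gaussian bumps
    centred on ``rain_peaks_doy`` (one peak: unimodal monsoon; two peaks:
    bimodal regime).  If ``rain_target_mar_sep`` is set, the amplitude is
    derived so the expected 1 Mar - 30 Sep sum equals the target; otherwise
    ``rain_amplitude`` (mm/day at peak) is used directly.

    Temperature is a single annual harmonic with the hottest day at
    ``t_peak_doy``; ``tmean_mar_sep`` fixes the expected Mar-Sep mean of the
    daily mean temperature and ``dtr`` the expected diurnal range.
    """

    rain_target_mar_sep: float | None = None
    rain_base: float = 0.5            # mm/day dry-season floor
    rain_amplitude: float | None = None
    rain_peaks_doy: tuple[float, ...] = (227.0,)
    rain_peak_width: float = 35.0     # days (Gaussian sd of each bump)
    tmean_mar_sep: float = 25.7       # degC, expected Mar-Sep daily-mean temp
    tmean_seasonal_amp: float = 1.8   # degC, annual harmonic amplitude
    t_peak_doy: float = 75.0          # hottest day (mid March, pre-monsoon)
    dtr: float = 9.9                  # degC, expected tmax - tmin


#: Defaults calibrated so an equal-area north/south domain has a national
#: Mar-Sep rainfall mean of ~1246 mm, diurnal range 9.9 degC and Mar-Sep mean
#: temperature 25.7 degC - the study's current-climate national summary.
NORTH_DEFAULT = ZoneClimate(rain_target_mar_sep=1050.0, rain_base=0.3,
                            rain_peaks_doy=(227.0,), rain_peak_width=40.0)
SOUTH_DEFAULT = ZoneClimate(rain_target_mar_sep=1442.0, rain_base=1.0,
                            rain_peaks_doy=(135.0, 280.0), rain_peak_width=30.0)


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth linking district yields to one agro-climatic driver.

    ``response`` maps the district mean of the driver variable to the
    expected yield (t/ha); it must be deterministic.  ``noise_sd`` is the
    standard deviation (t/ha) of the iid Gaussian year-to-year noise added
    on top (truncated at zero so yields stay non-negative).
    """

    driver: str = "rain_growing_season"
    response: Callable[[np.ndarray], np.ndarray] = field(
        default=lambda d: 0.5 + 3.0 * (d - np.min(d)) / max(np.ptp(d), 1e-12))
    noise_sd: float = 0.15
    seed: int = 0


# --------------------------------------------------------------------------
# seeding helpers
# --------------------------------------------------------------------------

def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent substream derived from the root seed and a component tag."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sd: float, length: float = 4.0) -> np.ndarray:
    """Zero-mean smooth Gaussian random field with pointwise sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=length, mode="nearest")
    s = smooth.std()
    if s < 1e-12:
        return np.zeros(shape)
    return sd * (smooth - smooth.mean()) / s


# --------------------------------------------------------------------------
# weather
# --------------------------------------------------------------------------

def _seasonal_kernel(doy: np.ndarray, peaks: Sequence[float], width: float) -> np.ndarray:
    """Sum of circularly wrapped Gaussian bumps, peak value ~1."""
    k = np.zeros_like(doy, dtype=float)
    for p in peaks:
        delta = np.minimum(np.abs(doy - p), 365.25 - np.abs(doy - p))
        k += np.exp(-0.5 * (delta / width) ** 2)
    return k


def _mar_sep_mask(index: pd.DatetimeIndex) -> np.ndarray:
    return (index.month >= 3) & (index.month <= 9)


def _zone_daily_rate(zone: ZoneClimate, index: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic mean rainfall rate (mm/day) for each calendar day."""
    doy = index.dayofyear.to_numpy().astype(float)
    kern = _seasonal_kernel(doy, zone.rain_peaks_doy, zone.rain_peak_width)
    if zone.rain_target_mar_sep is not None:
        ms = _mar_sep_mask(index)
        n_years = len(np.unique(index.year))
        kern_sum = kern[ms].sum() / n_years
        base_sum = zone.rain_base * ms.sum() / n_years
        amp = max((zone.rain_target_mar_sep - base_sum), 0.0) / max(kern_sum, 1e-9)
    else:
        amp = zone.rain_amplitude if zone.rain_amplitude is not None else 0.0
    return zone.rain_base + amp * kern


def _zone_daily_tmean(zone: ZoneClimate, index: pd.DatetimeIndex) -> np.ndarray:
    doy = index.dayofyear.to_numpy().astype(float)
    harm = np.cos(2 * np.pi * (doy - zone.t_peak_doy) / 365.25)
    ms = _mar_sep_mask(index)
    # anchor so the Mar-Sep mean of the harmonic contributes zero
    return zone.tmean_mar_sep + zone.tmean_seasonal_amp * (harm - harm[ms].mean())


def generate_weather(grid: GridSpec, years: int = 11, *,
                     north: ZoneClimate = NORTH_DEFAULT,
                     south: ZoneClimate = SOUTH_DEFAULT,
                     split_lat: float | None = None,
                     start_year: int = 2006,
                     rain_noise_frac: float = 0.5,
                     spatial_sd: float = 0.25,
                     temp_noise_sd: float = 0.8,
                     dtr_noise_sd: float = 1.0,
                     seed: int = 0) -> xr.Dataset:
    """Generate a daily weather grid (precip, tmax, tmin).

    Pixels at or above ``split_lat`` (default: grid mid-latitude) follow the
    ``north`` zone climate, the rest ``south``.  ``spatial_sd`` is the
    log-scale sd of smooth, month-specific lognormal wetness multipliers
    (mean 1) that give each pixel its own rainfall anomaly; ``rain_noise_frac``
    scales additive daily Gaussian noise proportional to the day's mean rate,
    truncated at zero.  The realized zonal Mar-Sep rainfall mean stays within
    a few percent of the configured target.

    Returns an :class:`xarray.Dataset` with variables ``precip`` (mm/day),
    ``tmax`` and ``tmin`` (degC) on dims ``(time, lat, lon)``.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if split_lat is None:
        split_lat = grid.mid_lat

    index = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D")
    nt = len(index)
    north_mask = grid.lats >= split_lat                      # per-row zone
    shape = (grid.ny, grid.nx)

    rate = np.empty((nt, grid.ny), dtype=np.float64)         # per (day, row)
    tmean_clim = np.empty_like(rate)
    for is_north, zone in ((True, north), (False, south)):
        rows = north_mask == is_north
        if rows.any():
            rate[:, rows] = _zone_daily_rate(zone, index)[:, None]
            tmean_clim[:, rows] = _zone_daily_tmean(zone, index)[:, None]
    rate = np.repeat(rate[:, :, None], grid.nx, axis=2)
    tmean_clim = np.repeat(tmean_clim[:, :, None], grid.nx, axis=2)

    # month-specific smooth wetness multipliers, lognormal with mean 1
    rng_p = _rng(seed, "weather-precip")
    wet = np.ones((12, grid.ny, grid.nx))
    if spatial_sd > 0:
        for m in range(12):
            f = _smooth_field(shape, rng_p, spatial_sd)
            wet[m] = np.exp(f - 0.5 * spatial_sd ** 2)
    month_idx = index.month.to_numpy() - 1
    mean_rate = rate * wet[month_idx]

    if rain_noise_frac > 0:
        noise = rng_p.standard_normal((nt,) + shape) * (rain_noise_frac * mean_rate)
        precip = np.maximum(mean_rate + noise, 0.0)
    else:
        precip = mean_rate

    # temperature: climatology + smooth pixel offset + daily weather noise
    rng_t = _rng(seed, "weather-temp")
    t_offset = _smooth_field(shape, rng_t, 0.7)
    dtr_offset = _smooth_field(shape, rng_t, 0.5)
    dtr_clim = np.where(north_mask, north.dtr, south.dtr)[None, :, None]
    tmean = tmean_clim + t_offset[None, :, :]
    if temp_noise_sd > 0:
        tmean = tmean + rng_t.standard_normal((nt,) + shape) * temp_noise_sd
    dtr = dtr_clim + dtr_offset[None, :, :]
    if dtr_noise_sd > 0:
        dtr = dtr + rng_t.standard_normal((nt,) + shape) * dtr_noise_sd
    dtr = np.maximum(dtr, 0.0)

    ds = xr.Dataset(
        {
            "precip": (("time", "lat", "lon"), (precip).astype(np.float32)),
            "tmax": (("time", "lat", "lon"), (tmean + dtr / 2).astype(np.float32)),
            "tmin": (("time", "lat", "lon"), (tmean - dtr / 2).astype(np.float32)),
        },
        coords={"time": index, "lat": grid.lats, "lon": grid.lons},
        attrs={"split_lat": float(split_lat), "seed": int(seed)},
    )
    ds["precip"].attrs["units"] = "mm/day"
    ds["tmax"].attrs["units"] = "degC"
    ds["tmin"].attrs["units"] = "degC"
    return ds


# --------------------------------------------------------------------------
# region: mask, zones, districts, soil
# --------------------------------------------------------------------------

def generate_region(grid: GridSpec, n_districts: int = 20, *,
                    split_lat: float | None = None,
                    mask_frac: float = 1.0,
                    soil_mean: float = 30.0, soil_sd: float = 8.0,
                    seed: int = 0) -> xr.Dataset:
    """Generate a study region: crop mask, zone labels, districts, soil carbon.

    Districts partition the masked pixels by nearest-seed (Voronoi) growth
    from ``n_districts`` randomly placed masked pixels, giving contiguous-ish
    regions that are each guaranteed non-empty.  ``zone`` is 1 (north) at or
    above ``split_lat`` and 0 (south) below.  ``mask_frac`` < 1 carves out a
    smooth random fraction of pixels as non-cropland.
    """
    if n_districts < 4:
        raise ValueError(f"need at least 4 districts, got {n_districts}")
    if split_lat is None:
        split_lat = grid.mid_lat
    rng = _rng(seed, "region")
    shape = (grid.ny, grid.nx)

    if mask_frac >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        f = _smooth_field(shape, rng, 1.0, length=2.0) + rng.standard_normal(shape) * 0.1
        thresh = np.quantile(f, 1.0 - mask_frac)
        mask = f >= thresh

    n_masked = int(mask.sum())
    if n_districts > n_masked:
        raise ValueError(f"{n_districts} districts exceed {n_masked} masked pixels")

    rows, cols = np.nonzero(mask)
    seed_idx = rng.choice(n_masked, size=n_districts, replace=False)
    seeds_rc = np.stack([rows[seed_idx], cols[seed_idx]], axis=1)  # (k, 2)
    pix = np.stack([rows, cols], axis=1)
    d2 = ((pix[:, None, :] - seeds_rc[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    districts = np.full(shape, -1, dtype=np.int32)
    districts[rows, cols] = assign

    zone = (grid.lats >= split_lat).astype(np.int8)[:, None] * np.ones((1, grid.nx), dtype=np.int8)

    soil = soil_mean + _smooth_field(shape, rng, soil_sd, length=3.0)
    soil = np.maximum(soil, 0.0)

    ds = xr.Dataset(
        {
            "crop_mask": (("lat", "lon"), mask),
            "zone": (("lat", "lon"), zone),
            "districts": (("lat", "lon"), districts),
            "soil_carbon": (("lat", "lon"), soil.astype(np.float32)),
        },
        coords={"lat": grid.lats, "lon": grid.lons},
        attrs={"split_lat": float(split_lat), "n_districts": int(n_districts),
               "seed": int(seed)},
    )
    ds["soil_carbon"].attrs["units"] = "t/ha"
    ds["zone"].attrs["legend"] = "0=south, 1=north"
    return ds


# --------------------------------------------------------------------------
# yields
# --------------------------------------------------------------------------

def generate_yields(weather: xr.Dataset, region: xr.Dataset, truth: TruthSpec,
                    *, crop: str = "maize",
                    years: Sequence[int] | None = None) -> pd.DataFrame:
    """Generate an annual district yield table driven by one known predictor.

    The driver named in ``truth.driver`` is computed from the weather and
    region grids with the same derivation the analysis itself uses, averaged
    per district over masked pixels; each district-year yield is
    ``truth.response(district driver mean)`` plus Gaussian noise of sd
    ``truth.noise_sd``, truncated at zero.  With ``noise_sd`` 0 the table is
    an exact deterministic function of the driver, which downstream
    parameter-recovery tests exploit.
    """
    from . import variables as agrovars

    varset = agrovars.assemble_variables(weather, region)
    if truth.driver not in varset.data_vars:
        raise KeyError(f"unknown driver variable {truth.driver!r}; "
                       f"choose one of {sorted(varset.data_vars)}")
    driver = varset[truth.driver].to_numpy()
    districts = region["districts"].to_numpy()
    mask = region["crop_mask"].to_numpy()

    dist_ids = np.unique(districts[mask & (districts >= 0)])
    means = np.array([np.nanmean(driver[(districts == d) & mask]) for d in dist_ids])
    expected = np.asarray(truth.response(means), dtype=float)

    if years is None:
        years = sorted(np.unique(weather["time"].dt.year.to_numpy()).tolist())
    years = list(years)

    rng = _rng(truth.seed, f"yields-{crop}")
    records = []
    for i, d in enumerate(dist_ids):
        noise = rng.standard_normal(len(years)) * truth.noise_sd if truth.noise_sd > 0 \
            else np.zeros(len(years))
        y = np.maximum(expected[i] + noise, 0.0)
        for yr, val in zip(years, y):
            records.append((int(d), crop, int(yr), float(val)))
    return pd.DataFrame(records, columns=["district", "crop", "year", "yield_t_ha"])
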