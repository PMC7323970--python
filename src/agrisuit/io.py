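"""File round-trips for the pipeline's artifacts.

Weather, region and predictor grids travel as CF-style NetCDF (classic
format, dims time/lat/lon); single- and multi-band rasters as plain TIFF
with a JSON sidecar carrying the grid axes, band names and no-data value;
yield tables as CSV with header ``district,crop,year,yield_t_ha``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

__all__ = [
    "write_netcdf", "read_netcdf",
    "write_raster", "read_raster",
    "write_yields", "read_yields",
]


def write_netcdf(ds: xr.Dataset, path: str | Path) -> Path:
    path = Path(path)
    ds = ds.copy()
    # classic NetCDF has no bool or int64; narrow the types
    for v in ds.data_vars:
        if ds[v].dtype == bool:
            ds[v] = ds[v].astype(np.int8)
        elif ds[v].dtype == np.int64:
            ds[v] = ds[v].astype(np.int32)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    if "crop_mask" in ds:
        ds["crop_mask"] = ds["crop_mask"].astype(bool)
    return ds


def write_raster(arr: np.ndarray | xr.DataArray | xr.Dataset, path: str | Path, *,
                 nodata: float | int = 0, band_names=None,
                 lats=None, lons=None) -> Path:
    """Write a (band, y, x) / (y, x) array or a Dataset of 2-D fields."""
    path = Path(path)
    if isinstance(arr, xr.Dataset):
        band_names = list(arr.data_vars)
        lats = arr["lat"].to_numpy()
        lons = arr["lon"].to_numpy()
        data = np.stack([arr[v].to_numpy() for v in band_names]).astype(np.float32)
    else:
        if isinstance(arr, xr.DataArray):
            lats = arr["lat"].to_numpy() if "lat" in arr.coords else lats
            lons = arr["lon"].to_numpy() if "lon" in arr.coords else lons
            arr = arr.to_numpy()
        data = np.asarray(arr)
        if data.ndim == 2:
            data = data[None]
    tifffile.imwrite(path, data)
    meta = {"nodata": nodata,
            "band_names": list(band_names) if band_names is not None
            else [f"band{i}" for i in range(data.shape[0])],
            "lat": None if lats is None else np.asarray(lats, float).tolist(),
            "lon": None if lons is None else np.asarray(lons, float).tolist()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def read_raster(path: str | Path):
    """Returns ``(data, meta)`` with data shaped (band, y, x)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data, meta


def write_yields(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.loc[:, ["district", "crop", "year", "yield_t_ha"]].to_csv(path, index=False)
    return path


def read_yields(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"district", "crop", "year", "yield_t_ha"}
    if not required.issubset(df.columns):
        raise ValueError(f"yield CSV must have columns {sorted(required)}")
    return df
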