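import numpy as np
import pandas as pd
import pytest
import xarray as xr

import agrisuit as ag


def make_weather(ny=3, nx=4, years=2, start_year=2006, precip=1.0,
                 tmax=30.0, tmin=20.0):
    """Hand-built weather grid with prescribed daily values.

    ``precip``/``tmax``/``tmin`` may be scalars or per-day vectors, letting
    tests construct exactly known window sums and means.
    """
    index = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31",
                          freq="D")
    nt = len(index)

    def grid(v):
        v = np.broadcast_to(np.asarray(v, dtype=float), (nt,))
        return np.broadcast_to(v[:, None, None], (nt, ny, nx)).copy()

    return xr.Dataset(
        {"precip": (("time", "lat", "lon"), grid(precip)),
         "tmax": (("time", "lat", "lon"), grid(tmax)),
         "tmin": (("time", "lat", "lon"), grid(tmin))},
        coords={"time": index, "lat": 4.5 + 0.05 * np.arange(ny),
                "lon": -1.0 + 0.05 * np.arange(nx)},
    )


def make_region(ny=3, nx=4, zone=0, n_districts=1):
    """Uniform-zone region with districts striped by column."""
    districts = (np.arange(nx)[None, :] % n_districts) * np.ones((ny, 1), dtype=int)
    return xr.Dataset(
        {"crop_mask": (("lat", "lon"), np.ones((ny, nx), dtype=bool)),
         "zone": (("lat", "lon"), np.full((ny, nx), zone, dtype=np.int8)),
         "districts": (("lat", "lon"), districts.astype(np.int32)),
         "soil_carbon": (("lat", "lon"), np.full((ny, nx), 25.0, dtype=np.float32))},
        coords={"lat": 4.5 + 0.05 * np.arange(ny), "lon": -1.0 + 0.05 * np.arange(nx)},
    )


@pytest.fixture(scope="session")
def grid20():
    return ag.GridSpec(20, 25)


@pytest.fixture(scope="session")
def weather20(grid20):
    return ag.synthetic.generate_weather(grid20, years=4, seed=11)


@pytest.fixture(scope="session")
def region20(grid20):
    return ag.synthetic.generate_region(grid20, n_districts=12, seed=11)


@pytest.fixture(scope="session")
def varset20(weather20, region20):
    return ag.variables.assemble_variables(weather20, region20)
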