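"""Yield-percentile suitability classes.

District yield series are reduced to multi-year means, quartered by the
25th/50th/75th percentiles of the district-mean distribution, and mapped to
four ordinal suitability classes: limited (1) < marginal (2) < moderate (3)
< optimal (4).  Optimal areas sit at or above the 75th percentile, limited
areas below the 25th.  Classes are then rasterized: every crop-masked pixel
inherits its district's class.

Boundary convention: intervals are half-open from below, with optimal closed
at q75 (y >= q75); for continuous yields any convention differs only on a
measure-zero set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "SuitabilityClass",
    "PercentileThresholds",
    "mean_yield",
    "thresholds",
    "assign_class",
    "rasterize_labels",
    "classify_crop",
]

NODATA = 0


class SuitabilityClass(IntEnum):
    LIMITED = 1
    MARGINAL = 2
    MODERATE = 3
    OPTIMAL = 4

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class PercentileThresholds:
    """Quartile cut points (t/ha) of the district-mean yield distribution."""

    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError(f"thresholds not ordered: {self}")


def mean_yield(yields: pd.DataFrame, crop: str) -> pd.Series:
    """Arithmetic mean yield per district over available years for one crop.

    Missing district-years simply drop out of the mean; the returned series
    carries the contributing year count in ``.attrs['n_years']``.
    """
    sub = yields[yields["crop"] == crop]
    if sub.empty:
        raise KeyError(f"crop {crop!r} absent from yield table")
    means = sub.groupby("district")["yield_t_ha"].mean()
    means.attrs["n_years"] = sub.groupby("district")["year"].nunique().to_dict()
    return means


def thresholds(means: pd.Series, *, interpolation: str = "linear") -> PercentileThresholds:
    """25th/50th/75th percentiles of the district means.

    ``interpolation`` is "linear" (default) or "nearest" for a nearest-rank
    definition; requires at least 4 districts.
    """
    vals = np.asarray(means, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 4:
        raise ValueError(f"need >= 4 districts with finite means, got {len(vals)}")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75], method=interpolation)
    return PercentileThresholds(float(q25), float(q50), float(q75))


def assign_class(y: float | np.ndarray, thr: PercentileThresholds):
    """Map mean yield(s) to a suitability class (rank 1-4).

    limited if y < q25; marginal if q25 <= y < q50; moderate if
    q50 <= y < q75; optimal if y >= q75.  NaN yields are rejected.
    """
    arr = np.asarray(y, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN yield cannot be classed")
    rank = np.select(
        [arr < thr.q25, arr < thr.q50, arr < thr.q75],
        [SuitabilityClass.LIMITED, SuitabilityClass.MARGINAL, SuitabilityClass.MODERATE],
        default=SuitabilityClass.OPTIMAL,
    )
    if np.isscalar(y) or arr.ndim == 0:
        return SuitabilityClass(int(rank))
    return rank.astype(np.uint8)


def rasterize_labels(district_classes: Mapping[int, int], region: xr.Dataset) -> np.ndarray:
    """Assign each crop-masked pixel its district's class rank.

    Returns a uint8 grid with ranks 1-4 on masked pixels and 0 (no-data)
    elsewhere.  Raises if a masked pixel's district has no class.
    """
    districts = region["districts"].to_numpy()
    mask = region["crop_mask"].to_numpy()
    present = np.unique(districts[mask & (districts >= 0)])
    missing = [int(d) for d in present if d not in district_classes]
    if missing:
        raise KeyError(f"districts without a class: {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.uint8)
    for d in present:
        lut[d] = int(district_classes[int(d)])
    out = np.full(districts.shape, NODATA, dtype=np.uint8)
    sel = mask & (districts >= 0)
    out[sel] = lut[districts[sel]]
    return out


def classify_crop(yields: pd.DataFrame, region: xr.Dataset, crop: str, *,
                  interpolation: str = "linear"):
    """Full classing for one crop: district means -> thresholds -> label grid.

    Returns ``(label_grid, thresholds, district_classes)``.
    """
    means = mean_yield(yields, crop)
    thr = thresholds(means, interpolation=interpolation)
    classes = {int(d): int(assign_class(v, thr)) for d, v in means.items()}
    grid = rasterize_labels(classes, region)
    return grid, thr, classes
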