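"""Climate-delta scenario projection.

Future predictor sets are built by adding per-GCM changes ("deltas") to the
baseline predictors: rainfall variables in mm, rainfall CV in percentage
points, temperature variables in degC, applied additively and uniformly in
space by default (a gridded mode accepts per-pixel delta rasters).  Rainfall
fields and the CV are clipped below at 0; soil organic carbon is held
unchanged, as no near-future projections exist for it.

The module ships the published national delta table for Ghana (four GCMs -
GFDL-ESM2M, HadGEM2-ES, IPSL-CM5A-LR, MIROC-ESM-CHEM - under RCP2.6 and
RCP8.5, mid-century vs 2006-2016 baseline) as ready-made inputs, plus the
baseline national summary they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "CLIMATE_VARS",
    "RAIN_VARS",
    "ClimateDelta",
    "GHANA_BASELINE",
    "GHANA_DELTAS",
    "apply_delta",
    "summarize_deltas",
    "mean_delta",
]

#: the seven climate-derived predictors a delta must cover (soil excluded)
CLIMATE_VARS = (
    "rain_growing_season", "rain_mar_sep", "rain_sowing_month", "rain_cv",
    "dtr_mar_sep", "tmean_growing_season", "tmean_mar_sep",
)

#: fields clipped at zero after applying a delta
RAIN_VARS = ("rain_growing_season", "rain_mar_sep", "rain_sowing_month", "rain_cv")


@dataclass(frozen=True)
class ClimateDelta:
    """Additive change in each climate variable for one GCM x scenario."""

    scenario: str
    model: str
    deltas: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CLIMATE_VARS) - set(self.deltas)
        extra = set(self.deltas) - set(CLIMATE_VARS)
        if missing or extra:
            raise ValueError(f"delta must cover exactly the climate variables; "
                             f"missing={sorted(missing)} unexpected={sorted(extra)}")


#: national current-climate summary the deltas are relative to
GHANA_BASELINE: Mapping[str, float] = {
    "rain_mar_sep": 1246.0, "rain_sowing_month": 228.0, "rain_cv": 69.0,
    "rain_growing_season": 558.0, "dtr_mar_sep": 9.9,
    "tmean_growing_season": 24.5, "tmean_mar_sep": 25.7,
}


def _delta(scenario, model, rain_ms, rain_sow, cv, rain_gs, dtr, tgs, tms):
    return ClimateDelta(scenario, model, {
        "rain_mar_sep": rain_ms, "rain_sowing_month": rain_sow, "rain_cv": cv,
        "rain_growing_season": rain_gs, "dtr_mar_sep": dtr,
        "tmean_growing_season": tgs, "tmean_mar_sep": tms})


#: published per-GCM national deltas for Ghana, mid-century
GHANA_DELTAS: tuple[ClimateDelta, ...] = (
    _delta("RCP2.6", "GFDL",   +52,  +2, -2, +30, -0.4, +1.5, +1.3),
    _delta("RCP2.6", "IPSL",   -43,  +3, +3, -14, -0.2, +1.8, +1.5),
    _delta("RCP2.6", "HADGEM",  -4, +10, +3, +14, -0.3, +2.2, +1.4),
    _delta("RCP2.6", "MIROC",  +58, +21, +6, +41, -0.4, +1.1, +1.3),
    _delta("RCP8.5", "GFDL",   +59, +27, +3, +40, -0.7, +2.1, +2.5),
    _delta("RCP8.5", "IPSL",  -117,  -3, +2, -29, -0.1, +2.8, +2.6),
    _delta("RCP8.5", "HADGEM", -13, +10, +3,  +7, -0.5, +1.5, +2.5),
    _delta("RCP8.5", "MIROC",  +86, +21, +2, +51, -0.3, +2.3, +1.8),
)


def apply_delta(baseline: xr.Dataset, delta: ClimateDelta | Mapping[str, float],
                ) -> xr.Dataset:
    """Additively shift the seven climate predictors; soil stays unchanged.

    ``delta`` values may be scalars (uniform national delta, the default
    mode) or grids matching the baseline (gridded mode).  Rainfall fields
    and the CV are clipped below at 0 after shifting.
    """
    deltas = delta.deltas if isinstance(delta, ClimateDelta) else delta
    missing = [v for v in CLIMATE_VARS if v not in deltas]
    if missing:
        raise KeyError(f"delta missing variable(s): {missing}")
    out = baseline.copy(deep=True)
    for v in CLIMATE_VARS:
        if v not in baseline.data_vars:
            raise KeyError(f"baseline missing variable {v!r}")
        shifted = baseline[v] + deltas[v]
        if v in RAIN_VARS:
            shifted = shifted.clip(min=0.0)
        shifted.attrs.update(baseline[v].attrs)
        out[v] = shifted
    if isinstance(delta, ClimateDelta):
        out.attrs["scenario"] = delta.scenario
        out.attrs["gcm"] = delta.model
    return out


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_deltas(deltas: Sequence[ClimateDelta], *,
                     decimals: int | Mapping[str, int] = 1) -> pd.DataFrame:
    """Multi-model summary per scenario and variable.

    For each scenario x variable: the arithmetic mean of the per-model
    deltas, the mean rounded half-up at the reporting precision
    (``decimals`` may be a single int or per-variable mapping), and the
    number of models agreeing in sign with the multi-model mean.
    """
    if not deltas:
        raise ValueError("no deltas to summarize")
    rows = []
    for scenario in dict.fromkeys(d.scenario for d in deltas):
        members = [d for d in deltas if d.scenario == scenario]
        for v in CLIMATE_VARS:
            vals = np.array([d.deltas[v] for d in members], dtype=float)
            mean = float(vals.mean())
            dec = decimals[v] if isinstance(decimals, Mapping) else decimals
            agree = int(np.sum(np.sign(vals) == np.sign(mean))) if mean != 0 \
                else int(np.sum(vals == 0))
            rows.append({"scenario": scenario, "variable": v,
                         "mean": mean, "mean_rounded": _round_half_up(mean, dec),
                         "n_models": len(members), "sign_agreement": agree})
    return pd.DataFrame(rows)


def mean_delta(deltas: Sequence[ClimateDelta], scenario: str) -> ClimateDelta:
    """Model-mean delta for one scenario (unrounded), usable in apply_delta."""
    members = [d for d in deltas if d.scenario == scenario]
    if not members:
        raise ValueError(f"no deltas for scenario {scenario!r}")
    means = {v: float(np.mean([d.deltas[v] for d in members])) for v in CLIMATE_VARS}
    return ClimateDelta(scenario, "model-mean", means)
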