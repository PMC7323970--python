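"""End-to-end orchestration: simulate -> derive -> class -> fit -> project.

A single declarative config drives every stage; all randomness descends from
one root seed, and a manifest records the config hash, package versions and
the SHA-256 of every artifact so a rerun with the same config and seed can
be verified byte-for-byte (the boosting library is forced single-threaded
for this reason).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classing, importance, io, metrics, model, multicrop, scenarios, synthetic
from . import variables as agrovars

__all__ = ["CropTruthConfig", "PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("agrisuit")

#: drivers and response direction chosen per crop so each crop's suitability
#: pattern has its own spatial signal, echoing the crop-specific importance
#: profile seen in national yield statistics
DEFAULT_CROPS: Mapping[str, Mapping] = {
    "maize": {"driver": "rain_mar_sep", "direction": 1.0},
    "sorghum": {"driver": "dtr_mar_sep", "direction": 1.0},
    "cassava": {"driver": "rain_growing_season", "direction": 1.0},
    "groundnut": {"driver": "rain_growing_season", "direction": 1.0},
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class CropTruthConfig:
    """Synthetic yield truth for one crop: a monotone linear response of the
    district-mean driver, rescaled to [y_base, y_base + y_range] t/ha."""

    driver: str = "rain_growing_season"
    direction: float = 1.0
    y_base: float = 0.5
    y_range: float = 3.0
    noise_sd: float = 0.15

    def truth(self, seed: int) -> synthetic.TruthSpec:
        sign, base, rng_ = self.direction, self.y_base, self.y_range

        def response(d: np.ndarray) -> np.ndarray:
            d = np.asarray(d, dtype=float) * sign
            lo, span = np.min(d), max(np.ptp(d), 1e-12)
            return base + rng_ * (d - lo) / span

        return synthetic.TruthSpec(driver=self.driver, response=response,
                                   noise_sd=self.noise_sd, seed=seed)


@dataclass
class PipelineConfig:
    # domain
    ny: int = 40
    nx: int = 50
    res: float = 0.05
    years: int = 11
    start_year: int = 2006
    n_districts: int = 20
    mask_frac: float = 0.95
    # crops and classing
    crops: Mapping[str, CropTruthConfig] = field(default_factory=lambda: {
        name: CropTruthConfig(**kw) for name, kw in DEFAULT_CROPS.items()})
    percentile_interpolation: str = "linear"
    # model
    split_fraction: float = 0.7
    tuning_grid: Mapping[str, Sequence] = field(default_factory=lambda: dict(model.DEFAULT_GRID))
    cv_folds: int = 5
    # scenarios and areas
    deltas: Sequence[scenarios.ClimateDelta] = scenarios.GHANA_DELTAS
    cell_area_mode: str = "equal"
    nominal_cell_km2: float = 30.25
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "crops" in raw:
            raw["crops"] = {name: CropTruthConfig(**(kw or {}))
                            for name, kw in raw["crops"].items()}
        if "deltas" in raw:
            raw["deltas"] = tuple(scenarios.ClimateDelta(**d) for d in raw["deltas"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage and write all artifacts under ``out_dir``.

    Per crop: thresholds CSV, class-label raster, fitted model, metrics and
    importance CSVs; per scenario: future suitability rasters (model-mean
    delta) and per-GCM area-change tables; multi-crop score rasters, count
    and area tables; and a ``manifest.json`` of artifact hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    scenario_ids = list(dict.fromkeys(d.scenario for d in config.deltas))

    def stage(name):
        log.info("stage %s", name)
        class _Ctx:
            def __enter__(self):
                return self
            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False
        return _Ctx()

    with stage("simulate"):
        grid = synthetic.GridSpec(config.ny, config.nx, res=config.res)
        weather = synthetic.generate_weather(grid, config.years,
                                             start_year=config.start_year,
                                             seed=config.seed)
        region = synthetic.generate_region(grid, config.n_districts,
                                           mask_frac=config.mask_frac,
                                           seed=config.seed)
        artifacts.append(io.write_netcdf(weather, out / "weather.nc"))
        artifacts.append(io.write_netcdf(region, out / "region.nc"))

    with stage("derive-vars"):
        varset = agrovars.assemble_variables(weather, region)
        artifacts.append(io.write_raster(varset, out / "variables.tif"))

    mask = region["crop_mask"].to_numpy()
    cell_area = multicrop.cell_areas((config.ny, config.nx),
                                     nominal_km2=config.nominal_cell_km2,
                                     lats=grid.lats, mode=config.cell_area_mode)

    current_maps: dict[str, np.ndarray] = {}
    future_maps: dict[str, dict[str, np.ndarray]] = {s: {} for s in scenario_ids}
    summary_rows = []

    for i, (crop, crop_cfg) in enumerate(config.crops.items()):
        with stage(f"classify[{crop}]"):
            yields = synthetic.generate_yields(
                weather, region, crop_cfg.truth(seed=config.seed + i), crop=crop)
            artifacts.append(io.write_yields(yields, out / f"yields_{crop}.csv"))
            labels, thr, _ = classing.classify_crop(
                yields, region, crop, interpolation=config.percentile_interpolation)
            pd.DataFrame([dataclasses.asdict(thr)]).to_csv(
                out / f"thresholds_{crop}.csv", index=False)
            artifacts.append(out / f"thresholds_{crop}.csv")
            artifacts.append(io.write_raster(labels, out / f"labels_{crop}.tif",
                                             lats=grid.lats, lons=grid.lons))

        with stage(f"train[{crop}]"):
            X, y, _ = model.samples_from_grids(varset, labels, mask)
            X_fit, X_test, y_fit, y_test = model.split_samples(
                X, y, config.split_fraction, seed=config.seed)
            clf = model.tune_and_fit(X_fit, y_fit, grid=config.tuning_grid,
                                     cv=config.cv_folds, seed=config.seed)
            clf.save(out / f"model_{crop}.json")
            artifacts.append(out / f"model_{crop}.json")

        with stage(f"evaluate[{crop}]"):
            proba = clf.predict_proba(X_test)
            pred = np.asarray(clf.classes)[np.argmax(proba, axis=1)]
            report = metrics.evaluate(y_test, pred, proba, classes=clf.classes)
            report.per_class.to_csv(out / f"class_metrics_{crop}.csv")
            artifacts.append(out / f"class_metrics_{crop}.csv")
            summary_rows.append(report.summary_row(crop))

        with stage(f"importance[{crop}]"):
            imp = importance.gain_importance(clf)
            frame = imp.to_frame(crop)
            for gname, groups in (("rain4", importance.GROUPS_RAIN4),
                                  ("rain3", importance.GROUPS_RAIN3)):
                gshares = importance.group_contributions(imp, groups)
                frame[f"group_{gname}"] = [
                    next(g for g, vs in groups.items() if v in vs)
                    for v in frame["variable"]]
                gshares.rename("share").rename_axis("group").to_csv(
                    out / f"importance_groups_{gname}_{crop}.csv")
                artifacts.append(out / f"importance_groups_{gname}_{crop}.csv")
            frame.to_csv(out / f"importance_{crop}.csv", index=False)
            artifacts.append(out / f"importance_{crop}.csv")

        with stage(f"project[{crop}]"):
            current_maps[crop], _ = model.predict_map(clf, varset, mask)
            artifacts.append(io.write_raster(
                current_maps[crop], out / f"suitability_{crop}_current.tif",
                lats=grid.lats, lons=grid.lons))
            cur_area = multicrop.area_table(current_maps[crop], cell_area,
                                            categories=[1, 2, 3, 4])
            per_gcm = {}
            for delta in config.deltas:
                fut_vars = scenarios.apply_delta(varset, delta)
                fut_map, _ = model.predict_map(clf, fut_vars, mask)
                per_gcm.setdefault(delta.scenario, []).append(
                    multicrop.area_table(fut_map, cell_area, categories=[1, 2, 3, 4]))
            for sc in scenario_ids:
                mean_vars = scenarios.apply_delta(
                    varset, scenarios.mean_delta(config.deltas, sc))
                future_maps[sc][crop], _ = model.predict_map(clf, mean_vars, mask)
                artifacts.append(io.write_raster(
                    future_maps[sc][crop], out / f"suitability_{crop}_{sc}.tif",
                    lats=grid.lats, lons=grid.lons))
                change = multicrop.change_table(cur_area, per_gcm[sc])
                change.to_csv(out / f"area_change_{crop}_{sc}.csv", index=False)
                artifacts.append(out / f"area_change_{crop}_{sc}.csv")

    with stage("evaluate-summary"):
        pd.concat(summary_rows, ignore_index=True).to_csv(
            out / "model_summary.csv", index=False)
        artifacts.append(out / "model_summary.csv")
        scenarios.summarize_deltas(config.deltas).to_csv(
            out / "delta_summary.csv", index=False)
        artifacts.append(out / "delta_summary.csv")

    with stage("multicrop"):
        crops = list(config.crops)
        for tag, maps in [("current", current_maps)] + \
                [(sc, future_maps[sc]) for sc in scenario_ids]:
            stackmaps = [maps[c] for c in crops]
            score = multicrop.combined_score(stackmaps)
            artifacts.append(io.write_raster(score, out / f"multicrop_score_{tag}.tif",
                                             lats=grid.lats, lons=grid.lons))
            counts = multicrop.count_by_class(stackmaps)
            rows = []
            for rank, cgrid in counts.items():
                for k in range(1, len(crops) + 1):
                    a = multicrop.area_table(
                        np.where(cgrid == k, 1, 0), cell_area, categories=[1]) \
                        if (cgrid == k).any() else None
                    rows.append({"suitability": classing.SuitabilityClass(rank).label,
                                 "n_crops": k,
                                 "area_km2": 0.0 if a is None else a["area_km2"][0]})
            pd.DataFrame(rows).to_csv(out / f"multicrop_counts_{tag}.csv", index=False)
            artifacts.append(out / f"multicrop_counts_{tag}.csv")
        _plot_maps(current_maps, future_maps, out, artifacts)

    with stage("manifest"):
        import sklearn
        import xgboost
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                         "xgboost": xgboost.__version__,
                         "sklearn": sklearn.__version__},
            "artifacts": {p.name: _sha256(Path(p)) for p in artifacts},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _plot_maps(current_maps, future_maps, out: Path, artifacts: list) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["#f0f0f0", "#d73027", "#fdae61", "#a6d96a", "#1a9850"])
    crops = list(current_maps)
    tags = ["current"] + list(future_maps)
    fig, axes = plt.subplots(len(crops), len(tags),
                             figsize=(3 * len(tags), 2.4 * len(crops)),
                             squeeze=False)
    for r, crop in enumerate(crops):
        for c, tag in enumerate(tags):
            m = current_maps[crop] if tag == "current" else future_maps[tag][crop]
            axes[r][c].imshow(m, cmap=cmap, vmin=0, vmax=4, origin="lower")
            axes[r][c].set_title(f"{crop} {tag}", fontsize=8)
            axes[r][c].axis("off")
    fig.tight_layout()
    fig.savefig(out / "suitability_maps.png", dpi=110)
    plt.close(fig)
    artifacts.append(out / "suitability_maps.png")
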