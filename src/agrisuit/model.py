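"""Four-class gradient-boosted suitability classifier.

A boosted-tree ensemble (XGBoost, softmax multiclass objective with
probability output) maps the eight biophysical predictors to the four
suitability classes.  Samples are split 70/30 (stratified by class) into a
fitting set and an independent test set; the number of boosting rounds,
maximum tree depth and learning rate are tuned by cross-validated grid
search on the fitting set, and the best setting is refit on the full
fitting set.  One independent model is trained per crop on an identical
predictor set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import xgboost as xgb
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .variables import VARIABLE_NAMES

__all__ = [
    "DEFAULT_GRID",
    "FittedClassifier",
    "split_samples",
    "tune_and_fit",
    "predict_map",
    "samples_from_grids",
]

#: default tuning grid: boosting rounds x max depth x learning rate
DEFAULT_GRID: Mapping[str, Sequence] = {
    "n_estimators": (50, 100, 200),
    "max_depth": (2, 4, 6),
    "learning_rate": (0.05, 0.1, 0.3),
}


@dataclass
class FittedClassifier:
    """A trained boosted-tree suitability model plus its provenance.

    ``classes`` are the suitability ranks in model output order and
    ``feature_names`` the predictor order the model expects; ``settings``
    records the tuned hyper-parameters and cross-validation accuracy.
    """

    booster: xgb.Booster
    classes: tuple
    feature_names: tuple
    settings: dict
    seed: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Hard class ranks (argmax of the class probabilities)."""
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = self._order(X)
        return self.booster.predict(xgb.DMatrix(X, nthread=1))

    def _order(self, X):
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise KeyError(f"missing predictor(s): {sorted(missing)}")
            return X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} predictors, "
                             f"got {X.shape[1]}")
        return X

    # -- persistence: xgboost's own JSON plus a metadata sidecar ------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.booster.save_model(str(path))
        meta = {"classes": [int(c) for c in self.classes],
                "feature_names": list(self.feature_names),
                "settings": self.settings, "seed": self.seed}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FittedClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(path))
        return cls(booster=booster, classes=tuple(meta["classes"]),
                   feature_names=tuple(meta["feature_names"]),
                   settings=meta["settings"], seed=meta["seed"])


def split_samples(X: pd.DataFrame, y: Sequence, fraction: float = 0.7, *,
                  seed: int = 0, stratify: bool = True):
    """Random split into a fitting set and an independent test set.

    Stratified by class (default) so all classes appear in both partitions;
    fitting-set size is round(fraction * n) up to stratification rounding.
    Returns ``(X_fit, X_test, y_fit, y_test)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if stratify and (counts < 2).any():
        bad = classes[counts < 2]
        raise ValueError(f"class(es) with < 2 samples cannot be stratified: {bad}")
    return train_test_split(X, y, train_size=fraction, random_state=seed,
                            stratify=y if stratify else None, shuffle=True)


def _make_estimator(seed: int, n_classes: int, **params) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        objective="multi:softprob", num_class=n_classes,
        tree_method="hist", n_jobs=1, random_state=seed,
        verbosity=0, **params)


def tune_and_fit(X: pd.DataFrame, y: Sequence, *,
                 grid: Mapping[str, Sequence] = DEFAULT_GRID,
                 cv: int = 5, seed: int = 0,
                 scoring: str = "accuracy") -> FittedClassifier:
    """Cross-validated grid search, then refit of the best setting.

    Tunes boosting rounds, maximum tree depth and learning rate (the grid is
    overridable) by ``cv``-fold stratified cross-validation on the fitting
    set, maximizing ``scoring`` (accuracy by default), then refits the
    winning setting on the full fitting set.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fit set is degenerate: a single class present")
    feature_names = tuple(X.columns) if isinstance(X, pd.DataFrame) else \
        tuple(f"x{i}" for i in range(np.asarray(X).shape[1]))
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y_enc = np.searchsorted(classes, y)

    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    search = GridSearchCV(_make_estimator(seed, len(classes)),
                          param_grid={k: list(v) for k, v in grid.items()},
                          scoring=scoring, cv=folds, n_jobs=1, refit=True)
    search.fit(Xm, y_enc)
    settings = {"best_params": search.best_params_,
                "cv_score": float(search.best_score_),
                "cv_folds": cv, "scoring": scoring,
                "grid": {k: list(v) for k, v in grid.items()}}
    return FittedClassifier(booster=search.best_estimator_.get_booster(),
                            classes=tuple(int(c) for c in classes),
                            feature_names=feature_names,
                            settings=settings, seed=seed)


def samples_from_grids(varset: xr.Dataset, labels: np.ndarray,
                       mask: np.ndarray | None = None):
    """Flatten predictor grids + label grid into a modelling table.

    Pixels must be crop-masked, labelled (rank > 0) and free of missing
    predictors.  Returns ``(X, y, pixel_index)`` where ``pixel_index`` holds
    the flat grid indices, letting predictions be written back spatially.
    """
    feat = np.stack([varset[v].to_numpy().ravel() for v in VARIABLE_NAMES], axis=1)
    lab = np.asarray(labels).ravel()
    ok = (lab > 0) & np.isfinite(feat).all(axis=1)
    if mask is not None:
        ok &= np.asarray(mask).ravel()
    X = pd.DataFrame(feat[ok], columns=VARIABLE_NAMES)
    return X, lab[ok].astype(int), np.flatnonzero(ok)


def predict_map(clf: FittedClassifier, varset: xr.Dataset,
                mask: np.ndarray | xr.DataArray):
    """Predict a suitability map and per-class probability grids.

    Returns ``(class_grid, proba)``: a uint8 rank grid (0 = no-data) and an
    :class:`xarray.DataArray` of probabilities with dims
    ``(suitability_class, lat, lon)``.  Probabilities sum to 1 per pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    missing = [v for v in clf.feature_names if v not in varset.data_vars]
    if missing:
        raise KeyError(f"missing predictor band(s): {missing}")
    feat = np.stack([varset[v].to_numpy().ravel() for v in clf.feature_names], axis=1)
    ok = mask.ravel() & np.isfinite(feat).all(axis=1)
    proba_flat = clf.predict_proba(feat[ok])

    ny, nx = mask.shape
    class_grid = np.zeros(ny * nx, dtype=np.uint8)
    class_grid[ok] = np.asarray(clf.classes, dtype=np.uint8)[np.argmax(proba_flat, axis=1)]
    proba = np.full((len(clf.classes), ny * nx), np.nan, dtype=np.float32)
    proba[:, ok] = proba_flat.T
    proba_da = xr.DataArray(
        proba.reshape(len(clf.classes), ny, nx),
        dims=("suitability_class", "lat", "lon"),
        coords={"suitability_class": list(clf.classes),
                "lat": varset["lat"], "lon": varset["lon"]},
        name="probability")
    return class_grid.reshape(ny, nx), proba_da
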