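"""Multi-crop aggregation: counts, rank-sum scores, area and change tables.

Single-crop suitability maps (pixel ranks 1=limited .. 4=optimal, 0=no-data)
are stacked to count, per pixel, how many crops sit at each suitability
level; summed into a combined score from 4 (very low) to 16 (very high) for
four crops; and paired into two-crop scores from 2 to 8 with categorical
labels (Ld-Ld .. Op-Op) from the unordered rank pair.  Area tables convert
category maps into km2 and percent-of-domain, and change tables difference
future against current areas (percentage points and km2), averaging over
GCMs when several are supplied.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANK_ABBR",
    "PAIR_CATEGORIES",
    "count_by_class",
    "combined_score",
    "pair_score",
    "pair_category_codes",
    "area_table",
    "change_table",
    "cell_areas",
]

NODATA = 0
RANK_ABBR = {1: "Ld", 2: "Mg", 3: "Md", 4: "Op"}

#: the ten unordered rank-pair categories, in rank-sum order
PAIR_CATEGORIES = tuple(
    f"{RANK_ABBR[a]}-{RANK_ABBR[b]}"
    for a in range(1, 5) for b in range(a, 5)
)


def _stack(maps: Sequence[np.ndarray]) -> np.ndarray:
    arrs = [np.asarray(m) for m in maps]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("suitability maps do not share a grid")
    return np.stack(arrs)


def _shared_valid(stack: np.ndarray) -> np.ndarray:
    return (stack != NODATA).all(axis=0)


def count_by_class(maps: Sequence[np.ndarray]) -> dict[int, np.ndarray]:
    """Per pixel and class level, the number of crops at that level.

    Returns ``{rank: count grid}`` for ranks 1-4; counts over the four
    levels sum to the number of crops at every valid pixel, and are 0
    wherever any map has no-data.
    """
    stack = _stack(maps)
    valid = _shared_valid(stack)
    return {c: np.where(valid, (stack == c).sum(axis=0), 0).astype(np.int16)
            for c in range(1, 5)}


def combined_score(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel sum of suitability ranks across crops (4-16 for 4 crops);
    0 where any crop has no-data."""
    stack = _stack(maps)
    valid = _shared_valid(stack)
    return np.where(valid, stack.sum(axis=0), NODATA).astype(np.int16)


def pair_score(map_a: np.ndarray, map_b: np.ndarray):
    """Two-crop rank sum (2-8) and unordered-pair category labels.

    Returns ``(score, codes)``: the rank-sum grid and an int grid indexing
    into :data:`PAIR_CATEGORIES` (-1 at no-data), so e.g. a (moderate,
    marginal) pixel scores 5 with category "Mg-Md".
    """
    stack = _stack([map_a, map_b])
    valid = _shared_valid(stack)
    score = np.where(valid, stack.sum(axis=0), NODATA).astype(np.int16)

    lo = np.minimum(map_a, map_b)
    hi = np.maximum(map_a, map_b)
    lut = {(a, b): i for i, (a, b) in enumerate(
        (a, b) for a in range(1, 5) for b in range(a, 5))}
    codes = np.full(score.shape, -1, dtype=np.int16)
    for (a, b), i in lut.items():
        codes[valid & (lo == a) & (hi == b)] = i
    return score, codes


def pair_category_codes(codes: np.ndarray) -> np.ndarray:
    """Decode a category-code grid into its string labels ('' at no-data)."""
    labels = np.array([""] + list(PAIR_CATEGORIES), dtype=object)
    return labels[np.asarray(codes) + 1]


def cell_areas(shape: tuple[int, int], *, nominal_km2: float = 30.25,
               lats: np.ndarray | None = None, mode: str = "equal") -> np.ndarray:
    """Per-cell area grid (km2).

    ``"equal"`` assigns ``nominal_km2`` everywhere (default ~0.05 degree
    cells near the equator); ``"cosine"`` scales by cos(latitude) for
    geographic grids, normalized so the domain-mean cell keeps the nominal
    area.
    """
    if mode == "equal":
        return np.full(shape, nominal_km2, dtype=float)
    if mode == "cosine":
        if lats is None:
            raise ValueError("cosine mode needs the latitude axis")
        w = np.cos(np.deg2rad(np.asarray(lats, dtype=float)))
        w = w / w.mean()
        return nominal_km2 * np.repeat(w[:, None], shape[1], axis=1)
    raise ValueError(f"unknown cell-area mode {mode!r}")


def area_table(category_map: np.ndarray, cell_area: float | np.ndarray, *,
               categories: Sequence | None = None,
               labels: Mapping | None = None) -> pd.DataFrame:
    """Area (km2) and percent of valid domain per map category.

    ``category_map`` is any integer category grid with 0 (or, for pair
    category codes, -1) as no-data; ``categories`` fixes the row set (useful
    so current/future tables share categories even when a class is absent).
    """
    cat = np.asarray(category_map)
    area = np.broadcast_to(np.asarray(cell_area, dtype=float), cat.shape)
    if cat.min() < 0:     # pair-category codes: -1 is no-data, 0 is a category
        valid = cat >= 0
    else:
        valid = cat > 0
    total = float(area[valid].sum())
    if total <= 0:
        raise ValueError("zero valid area")
    if categories is None:
        categories = sorted(np.unique(cat[valid]).tolist())
    rows = []
    for c in categories:
        a = float(area[valid & (cat == c)].sum())
        rows.append({"category": labels[c] if labels else c,
                     "area_km2": a, "percent": 100.0 * a / total})
    return pd.DataFrame(rows)


def change_table(current: pd.DataFrame,
                 future: pd.DataFrame | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Future-minus-current area change per category.

    ``future`` may be one table or several (one per GCM), in which case the
    change columns are the mean across GCMs.  Columns: current/future area
    and percent, ``change_pp`` (percentage points) and ``change_km2``.
    """
    futures = [future] if isinstance(future, pd.DataFrame) else list(future)
    cur = current.set_index("category")
    changes_pp, changes_km2, fut_pct, fut_area = [], [], [], []
    for f in futures:
        fi = f.set_index("category")
        if not fi.index.equals(cur.index):
            raise ValueError("current and future tables have different categories")
        changes_pp.append(fi["percent"] - cur["percent"])
        changes_km2.append(fi["area_km2"] - cur["area_km2"])
        fut_pct.append(fi["percent"])
        fut_area.append(fi["area_km2"])
    out = pd.DataFrame({
        "current_area_km2": cur["area_km2"],
        "current_percent": cur["percent"],
        "future_area_km2": pd.concat(fut_area, axis=1).mean(axis=1),
        "future_percent": pd.concat(fut_pct, axis=1).mean(axis=1),
        "change_pp": pd.concat(changes_pp, axis=1).mean(axis=1),
        "change_km2": pd.concat(changes_km2, axis=1).mean(axis=1),
    })
    return out.reset_index()
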