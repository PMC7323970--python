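"""Gain-based variable importance for the boosted-tree suitability models.

The gain of a variable is the total loss reduction attributed to splits on
it, summed over every tree in the ensemble.  Shares are standardized so the
eight variables sum to 1 (a max-normalized variant is available); variables
never used by any split receive 0.  Grouped contributions aggregate shares
into rainfall-based, temperature-based and soil groups.  Because the prose
convention for whether rainfall variability belongs to the rainfall group is
ambiguous in the field, both a 4-variable rainfall grouping (CV included)
and a 3-variable one (CV as its own group) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .model import FittedClassifier

__all__ = [
    "ImportanceReport",
    "gain_importance",
    "group_contributions",
    "GROUPS_RAIN4",
    "GROUPS_RAIN3",
]

#: rainfall group includes the rainfall CV
GROUPS_RAIN4: Mapping[str, tuple] = {
    "rainfall": ("rain_growing_season", "rain_mar_sep", "rain_sowing_month", "rain_cv"),
    "temperature": ("dtr_mar_sep", "tmean_growing_season", "tmean_mar_sep"),
    "soil": ("soil_organic_carbon",),
}

#: rainfall group restricted to the three rainfall sums; CV stands alone
GROUPS_RAIN3: Mapping[str, tuple] = {
    "rainfall": ("rain_growing_season", "rain_mar_sep", "rain_sowing_month"),
    "rainfall_variability": ("rain_cv",),
    "temperature": ("dtr_mar_sep", "tmean_growing_season", "tmean_mar_sep"),
    "soil": ("soil_organic_carbon",),
}


@dataclass
class ImportanceReport:
    """Per-variable gain shares for one crop's model; shares sum to 1."""

    shares: pd.Series              # index: variable name
    normalization: str = "sum"

    def ranked(self) -> pd.Series:
        return self.shares.sort_values(ascending=False)

    def to_frame(self, crop: str = "") -> pd.DataFrame:
        df = self.shares.rename("share").rename_axis("variable").reset_index()
        df.insert(0, "crop", crop)
        return df


def gain_importance(clf: FittedClassifier, *, normalization: str = "sum") -> ImportanceReport:
    """Normalized total-gain importance of each predictor.

    Sums each variable's split gains across all trees of the ensemble, then
    normalizes: ``"sum"`` (default) divides by the total so shares sum to 1;
    ``"max"`` divides by the largest raw gain so the top variable scores 1.
    """
    booster = clf.booster
    if booster.num_boosted_rounds() == 0:
        raise ValueError("classifier has no trees")
    raw = booster.get_score(importance_type="total_gain")
    # xgboost keys are feature names if set, else f0, f1, ...
    gains = []
    for i, name in enumerate(clf.feature_names):
        gains.append(raw.get(name, raw.get(f"f{i}", 0.0)))
    s = pd.Series(gains, index=list(clf.feature_names), dtype=float)
    if normalization == "sum":
        total = s.sum()
        if total <= 0:
            raise ValueError("ensemble attributes zero total gain")
        s = s / total
    elif normalization == "max":
        s = s / s.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ImportanceReport(shares=s, normalization=normalization)


def group_contributions(report: ImportanceReport,
                        grouping: Mapping[str, Sequence[str]] = GROUPS_RAIN4) -> pd.Series:
    """Sum shares within variable groups; the grouping must cover each
    variable exactly once."""
    members = [v for group in grouping.values() for v in group]
    if sorted(members) != sorted(report.shares.index):
        missing = set(report.shares.index) - set(members)
        extra = set(members) - set(report.shares.index)
        dup = {v for v in members if members.count(v) > 1}
        raise ValueError("grouping must partition the variables; "
                         f"missing={sorted(missing)} unknown={sorted(extra)} "
                         f"duplicated={sorted(dup)}")
    return pd.Series({g: float(report.shares[list(vs)].sum()) if len(vs) else 0.0
                      for g, vs in grouping.items()})
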