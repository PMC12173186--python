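"""Obstacle-degree decomposition of each object's capacity shortfall.

For evaluation object i, indicator j contributes the share

    P_ij = (1 - y_ij) w_j / sum_k (1 - y_ik) w_k x 100%

of the total weighted shortfall, where y is the normalized value and w
the combined indicator weight. Degrees sum to 100% per object; an
indicator already at its best (y = 1) contributes nothing. The top-k
degrees identify the factors most restricting improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import RegcapError
from .panel_model import Category
from .preprocessing import NormalizedPanel
from .weighting import WeightSet

__all__ = [
    "ObstacleReport",
    "obstacle_degrees",
    "top_obstacles",
    "regional_obstacle_summary",
]

SummaryMethod = Literal["mean_of_members", "mean_profile"]


@dataclass
class ObstacleReport:
    """Obstacle degrees (percent) per evaluation object.

    ``degrees`` has a (region, year) index and one column per indicator;
    each row sums to 100 except objects listed in ``no_obstacle``
    (normalized profile all ones: zero shortfall, degrees all 0).
    """

    degrees: pd.DataFrame
    no_obstacle: list[tuple[str, int]] = field(default_factory=list)

    def for_object(self, region: str, year: int) -> pd.Series:
        return self.degrees.loc[(region, year)]


def obstacle_degrees(normalized: NormalizedPanel, weights: WeightSet) -> ObstacleReport:
    """Shortfall-share decomposition for every object of the panel."""
    y = normalized.values
    w = weights.combined.reindex(y.columns)
    if w.isna().any():
        missing = list(w[w.isna()].index)
        raise RegcapError(f"no combined weight for indicator(s): {missing}")
    numer = (1.0 - y).mul(w, axis=1)
    totals = numer.sum(axis=1)
    no_obstacle = [(r, int(t)) for r, t in totals[totals == 0].index]
    safe = totals.replace(0.0, np.nan)
    degrees = numer.div(safe, axis=0).fillna(0.0) * 100.0
    return ObstacleReport(degrees=degrees, no_obstacle=no_obstacle)


def top_obstacles(degrees: pd.Series, k: int) -> list[tuple[str, float]]:
    """The k largest obstacle degrees, descending.

    Ties are broken by indicator (schema) order — the order of the input
    Series — so results are deterministic. ``k`` beyond the number of
    indicators returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = degrees.sort_values(ascending=False, kind="stable")
    return [(str(j), float(v)) for j, v in order.iloc[:k].items()]


def regional_obstacle_summary(
    report: ObstacleReport,
    categories: Mapping[str, Category],
    method: SummaryMethod = "mean_of_members",
    *,
    normalized: NormalizedPanel | None = None,
    weights: WeightSet | None = None,
) -> pd.DataFrame:
    """Aggregate per-object degrees into one vector per regional category.

    ``mean_of_members`` (default): arithmetic mean of member objects'
    degree vectors, renormalized to 100%. ``mean_profile``: obstacle
    degrees of each category's mean normalized profile (requires
    ``normalized`` and ``weights``). Output rows sum to 100 per
    (category, year).
    """
    if method == "mean_of_members":
        deg = report.degrees
        keys = [
            [Category(categories[r]).value for r in deg.index.get_level_values("region")],
            deg.index.get_level_values("year"),
        ]
        mean = deg.groupby(keys).mean()
        mean.index.names = ["category", "year"]
    elif method == "mean_profile":
        if normalized is None or weights is None:
            raise ValueError("mean_profile summary needs normalized and weights")
        y = normalized.values
        keys = [
            [Category(categories[r]).value for r in y.index.get_level_values("region")],
            y.index.get_level_values("year"),
        ]
        profile = y.groupby(keys).mean()
        profile.index.names = ["category", "year"]
        w = weights.combined.reindex(profile.columns)
        numer = (1.0 - profile).mul(w, axis=1)
        totals = numer.sum(axis=1).replace(0.0, np.nan)
        mean = numer.div(totals, axis=0).fillna(0.0) * 100.0
    else:
        raise ValueError(f"unknown summary method {method!r}")
    row_sums = mean.sum(axis=1).replace(0.0, np.nan)
    return mean.div(row_sums, axis=0).fillna(0.0) * 100.0
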