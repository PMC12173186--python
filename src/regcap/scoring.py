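"""Dimension scores, composite index, ranking and group descriptives.

A dimension score is the within-dimension weighted mean of its
normalized indicators, s_d = sum_{j in d} w_j y_j; the composite is the
dimension-weighted sum sum_d W_d s_d. Published score tables print three
decimals and rank ties by competition ranking ("1, 2, 2, 4"), so the
table-facing operations here round half-up at 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up
from .panel_model import Category, IndicatorSchema
from .preprocessing import NormalizedPanel
from .weighting import WeightSet

__all__ = [
    "ScoreTable",
    "dimension_scores",
    "composite_scores",
    "score_panel",
    "rank_regions",
    "count_above_mean",
    "group_means",
    "trend_table",
]


def dimension_scores(
    normalized: NormalizedPanel, weights: WeightSet, schema: IndicatorSchema
) -> pd.DataFrame:
    """Per (region, year): s_d = sum of member within-dimension weights x y."""
    out = {}
    for dim in schema.dimension_ids:
        members = schema.members(dim)
        w = weights.within_dimension[members]
        out[dim] = normalized.values[members].mul(w, axis=1).sum(axis=1)
    return pd.DataFrame(out)


def composite_scores(dim_scores: pd.DataFrame, weights: WeightSet) -> pd.Series:
    """Composite index: dimension-weighted sum of dimension scores."""
    w = weights.dimension_weights.reindex(dim_scores.columns)
    comp = dim_scores.mul(w, axis=1).sum(axis=1)
    comp.name = "composite"
    return comp


def rank_regions(composite: pd.Series, decimals: int | None = 3) -> pd.Series:
    """Descending competition ranking, tied at printed precision.

    Equal values (after half-up rounding at ``decimals``) share a rank
    and the following ranks are skipped; ``decimals=None`` ranks the raw
    values.
    """
    vals = round_half_up(composite, decimals) if decimals is not None else composite
    ranks = vals.rank(method="min", ascending=False).astype(int)
    ranks.name = "rank"
    return ranks


@dataclass
class ScoreTable:
    """Tidy score table: one row per (region, year) with category, the
    dimension scores, composite and within-year rank."""

    frame: pd.DataFrame
    dimension_columns: list[str]

    @property
    def score_columns(self) -> list[str]:
        return self.dimension_columns + ["composite"]

    def year_slice(self, year: int) -> pd.DataFrame:
        return self.frame[self.frame["year"] == year]


def score_panel(
    normalized: NormalizedPanel, weights: WeightSet, schema: IndicatorSchema
) -> ScoreTable:
    """Score every evaluation object and rank regions within each year."""
    dims = dimension_scores(normalized, weights, schema)
    comp = composite_scores(dims, weights)
    frame = dims.copy()
    frame["composite"] = comp
    frame = frame.reset_index()
    frame.insert(1, "category", frame["region"].map(lambda r: normalized.categories[r].value))
    frame["rank"] = (
        frame.groupby("year")["composite"].transform(lambda s: rank_regions(s).to_numpy())
    )
    return ScoreTable(frame=frame, dimension_columns=list(schema.dimension_ids))


def count_above_mean(values, decimals: int | None = None) -> int:
    """Count entries strictly greater than the arithmetic mean.

    With ``decimals`` set, both the values and the mean are first rounded
    half-up to that precision — the convention needed to compare against
    published tables printed at fixed precision.
    """
    vals = np.asarray(pd.Series(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty value vector")
    mean = vals.mean()
    if decimals is not None:
        vals = np.asarray(round_half_up(vals, decimals))
        mean = round_half_up(mean, decimals)
    return int((vals > mean).sum())


def group_means(
    frame: pd.DataFrame,
    columns: list[str],
    grouping: str = "category",
) -> pd.DataFrame:
    """Mean and sample SD (n-1) per group for each score column.

    ``grouping="national"`` pools every row into one group. Singleton
    groups have undefined sample SD, reported as 0 and flagged.
    """
    if grouping == "national":
        frame = frame.assign(_group="national")
        key = "_group"
    else:
        key = grouping
    records = []
    for group, block in frame.groupby(key, sort=False):
        n = len(block)
        for col in columns:
            mean = float(block[col].mean())
            sd = float(block[col].std(ddof=1)) if n > 1 else 0.0
            records.append(
                {
                    "group": group,
                    "column": col,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "sd_defined": n > 1,
                }
            )
    return pd.DataFrame.from_records(records)


def trend_table(
    scores: ScoreTable, grouping: str = "category", include_national: bool = True
) -> pd.DataFrame:
    """Year-ordered group-mean series with year-over-year deltas.

    Tidy output: group, column, year, mean, delta (NaN for the first
    year) — the tabular form behind dynamic-trend panels.
    """
    pieces = []
    for year, block in scores.frame.groupby("year"):
        gm = group_means(block, scores.score_columns, grouping=grouping)
        gm["year"] = year
        pieces.append(gm)
        if include_national:
            nat = group_means(block, scores.score_columns, grouping="national")
            nat["year"] = year
            pieces.append(nat)
    table = pd.concat(pieces, ignore_index=True)
    table = table.sort_values(["group", "column", "year"]).reset_index(drop=True)
    table["delta"] = table.groupby(["group", "column"])["mean"].diff()
    return table[["group", "column", "year", "mean", "sd", "delta"]]
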