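"""Missing-data interpolation and dimensionless (min-max) normalization.

Positive indicators map through ``(x - x_min) / (x_max - x_min)``,
negative ones through ``(x_max - x) / (x_max - x_min)``, so every
normalized value lies in [0, 1] with 1 always meaning "better". Bounds
are taken per indicator either over the pooled panel (default: scores
stay comparable across years) or within each year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import PreprocessingError
from .panel_model import Category, IndicatorSchema, Nature, RawPanel

__all__ = [
    "NormalizedPanel",
    "ImputedCell",
    "ConstantIndicatorWarning",
    "interpolate_missing",
    "normalize_value",
    "normalize_panel",
]

Scope = Literal["pooled", "per_year"]


class ConstantIndicatorWarning(UserWarning):
    """An indicator is constant over its normalization group."""


@dataclass(frozen=True)
class ImputedCell:
    region: str
    year: int
    indicator: str
    value: float
    method: str  # "linear" | "nearest"


@dataclass
class NormalizedPanel:
    """Normalized values in [0, 1] plus the bounds and scope that produced them.

    ``values`` has a (region, year) MultiIndex and one column per
    indicator, in schema order. ``bounds`` records the (x_min, x_max)
    pair actually used per indicator (per year when scope="per_year",
    index then is (year, indicator)).
    """

    values: pd.DataFrame
    bounds: pd.DataFrame
    scope: Scope
    categories: dict[str, Category]

    @property
    def objects(self) -> list[tuple[str, int]]:
        return [(r, int(y)) for r, y in self.values.index]

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["region", "year", "indicator", "value"]
        long.insert(1, "category", long["region"].map(lambda r: self.categories[r].value))
        return long


def interpolate_missing(panel: RawPanel) -> tuple[RawPanel, list[ImputedCell]]:
    """Fill gaps per (region, indicator) series along the year axis.

    Interior gaps: linear interpolation against the year value (robust to
    unevenly spaced years). Boundary gaps: nearest observed value. A
    series with no observation at all cannot be filled and is an error.
    """
    wide = panel.frame.pivot_table(
        index="year", columns=["region", "indicator"], values="value", dropna=False
    ).sort_index()
    all_missing = wide.columns[wide.isna().all(axis=0)]
    if len(all_missing):
        region, indicator = all_missing[0]
        raise PreprocessingError(
            f"series ({region!r}, {indicator!r}) is entirely missing; "
            "cannot interpolate"
        )
    was_missing = wide.isna()
    interior = wide.interpolate(method="index", limit_area="inside", axis=0)
    filled = interior.ffill().bfill()

    log: list[ImputedCell] = []
    for col in wide.columns[was_missing.any(axis=0)]:
        region, indicator = col
        for year in wide.index[was_missing[col]]:
            method = "linear" if not np.isnan(interior.at[year, col]) else "nearest"
            log.append(
                ImputedCell(region, int(year), indicator, float(filled.at[year, col]), method)
            )

    long = filled.stack(["region", "indicator"], future_stack=True).rename("value").reset_index()
    categories = {r.region: r.category.value for r in panel.regions}
    long["category"] = long["region"].map(categories)
    long = long[["region", "category", "year", "indicator", "value"]]
    new_panel = RawPanel(
        frame=long,
        regions=panel.regions,
        years=panel.years,
        indicators=panel.indicators,
    )
    return new_panel, log


def normalize_value(x: float, x_min: float, x_max: float, nature: Nature) -> float:
    """Min-max normalize a single value given its bounds and direction."""
    if x_min >= x_max:
        raise PreprocessingError(f"degenerate bounds: x_min={x_min} >= x_max={x_max}")
    if not (x_min <= x <= x_max):
        raise PreprocessingError(f"value {x} outside bounds [{x_min}, {x_max}]")
    if Nature(nature) is Nature.POSITIVE:
        return (x - x_min) / (x_max - x_min)
    return (x_max - x) / (x_max - x_min)


def _normalize_block(
    block: pd.DataFrame, schema: IndicatorSchema, clip: bool
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize one scope group; returns (values, bounds)."""
    lo = block.min(axis=0)
    hi = block.max(axis=0)
    out = pd.DataFrame(index=block.index, columns=block.columns, dtype=float)
    for ind in block.columns:
        nature = schema.indicator(ind).nature
        span = hi[ind] - lo[ind]
        if span == 0:
            warnings.warn(
                f"indicator {ind!r} is constant ({lo[ind]!r}); normalized to 0.5 — "
                "the entropy stage will assign it zero weight",
                ConstantIndicatorWarning,
                stacklevel=3,
            )
            out[ind] = 0.5
            continue
        if nature is Nature.POSITIVE:
            col = (block[ind] - lo[ind]) / span
        else:
            col = (hi[ind] - block[ind]) / span
        if clip:
            outside = (col < 0) | (col > 1)
            if outside.any():
                warnings.warn(
                    f"{int(outside.sum())} value(s) of {ind!r} outside frozen bounds; "
                    "clipped to [0, 1]",
                    UserWarning,
                    stacklevel=3,
                )
            col = col.clip(0.0, 1.0)
        out[ind] = col
    bounds = pd.DataFrame({"x_min": lo, "x_max": hi})
    bounds.index.name = "indicator"
    return out, bounds


def normalize_panel(
    panel: RawPanel,
    schema: IndicatorSchema,
    scope: Scope = "pooled",
    bounds: pd.DataFrame | None = None,
) -> NormalizedPanel:
    """Normalize a complete panel per indicator over the stated scope.

    With ``bounds`` given (a frame indexed by indicator with columns
    x_min/x_max, e.g. frozen from a reference period), those bounds are
    applied instead and out-of-sample values are clipped to [0, 1] with a
    warning.
    """
    wide = panel.wide()
    if wide.isna().any().any():
        missing = panel.missing_cells()
        raise PreprocessingError(
            f"panel has {len(missing)} missing cell(s) — run interpolate_missing first; "
            f"first: {missing[0]}"
        )
    categories = {r.region: r.category for r in panel.regions}

    if bounds is not None:
        lo = bounds["x_min"].reindex(wide.columns)
        hi = bounds["x_max"].reindex(wide.columns)
        values = _frozen_normalize(wide, lo, hi, schema)
        return NormalizedPanel(
            values=values, bounds=bounds.copy(), scope="pooled", categories=categories
        )

    if scope == "pooled":
        values, out_bounds = _normalize_block(wide, schema, clip=False)
    elif scope == "per_year":
        parts = []
        bparts = []
        for year, block in wide.groupby(level="year"):
            vals, b = _normalize_block(block, schema, clip=False)
            parts.append(vals)
            b = b.assign(year=year).set_index("year", append=True).reorder_levels(["year", "indicator"])
            bparts.append(b)
        values = pd.concat(parts).sort_index()
        out_bounds = pd.concat(bparts)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return NormalizedPanel(values=values, bounds=out_bounds, scope=scope, categories=categories)


def _frozen_normalize(
    wide: pd.DataFrame, lo: pd.Series, hi: pd.Series, schema: IndicatorSchema
) -> pd.DataFrame:
    out = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for ind in wide.columns:
        span = hi[ind] - lo[ind]
        if span == 0:
            out[ind] = 0.5
            continue
        if schema.indicator(ind).nature is Nature.POSITIVE:
            col = (wide[ind] - lo[ind]) / span
        else:
            col = (hi[ind] - wide[ind]) / span
        outside = (col < 0) | (col > 1)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} value(s) of {ind!r} outside frozen bounds; clipped",
                UserWarning,
                stacklevel=3,
            )
            col = col.clip(0.0, 1.0)
        out[ind] = col
    return out
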