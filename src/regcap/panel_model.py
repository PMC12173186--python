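"""Domain types and IO for indicator schemas, raw panels, expert scores.

The canonical exchange format is tidy long CSV with columns
``region, category, year, indicator, value`` (UTF-8, ``.`` decimal).
Schemas are YAML with ``dimensions`` and ``indicators`` lists. Missing
panel cells are kept as explicit NaN — imputation is a deliberate
preprocessing step (:mod:`regcap.preprocessing`), never a side effect of
reading.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import PanelError, SchemaError

__all__ = [
    "Nature",
    "Category",
    "Dimension",
    "IndicatorDef",
    "IndicatorSchema",
    "RegionInfo",
    "RawPanel",
    "ExpertScoreTable",
    "VigilanceSeries",
    "ValidationIssue",
    "ValidationReport",
    "read_schema",
    "schema_from_dict",
    "read_panel",
    "panel_from_frame",
    "write_panel",
    "validate_panel",
    "read_expert_scores",
    "read_vigilance",
]

PANEL_COLUMNS = ("region", "category", "year", "indicator", "value")


class Nature(str, enum.Enum):
    """Direction of an indicator: larger-is-better or smaller-is-better."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class Category(str, enum.Enum):
    """Economic-belt classification of China's provincial-level regions."""

    EASTERN = "eastern"
    CENTRAL = "central"
    WESTERN = "western"


@dataclass(frozen=True)
class Dimension:
    """A capacity dimension grouping several indicators.

    ``weight`` is an optional frozen dimension-level weight (used when a
    published weight system is shipped with the schema instead of being
    re-derived from data).
    """

    id: str
    name: str
    weight: float | None = None


@dataclass(frozen=True)
class IndicatorDef:
    """One evaluation indicator.

    ``weight`` is the optional frozen *within-dimension* weight.
    """

    id: str
    name: str
    unit: str
    dimension: str
    nature: Nature
    weight: float | None = None


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered two-level indicator system: dimensions and their indicators."""

    dimensions: tuple[Dimension, ...]
    indicators: tuple[IndicatorDef, ...]

    def __post_init__(self) -> None:
        dim_ids = [d.id for d in self.dimensions]
        if len(set(dim_ids)) != len(dim_ids):
            raise SchemaError(f"duplicate dimension ids: {sorted(dim_ids)}")
        ind_ids = [i.id for i in self.indicators]
        if len(set(ind_ids)) != len(ind_ids):
            dupes = sorted({i for i in ind_ids if ind_ids.count(i) > 1})
            raise SchemaError(f"duplicate indicator ids: {dupes}")
        for ind in self.indicators:
            if ind.dimension not in dim_ids:
                raise SchemaError(
                    f"indicator {ind.id!r} references undeclared dimension {ind.dimension!r}"
                )
        for d in self.dimensions:
            if not any(i.dimension == d.id for i in self.indicators):
                raise SchemaError(f"dimension {d.id!r} has no indicators")

    @property
    def m(self) -> int:
        """Number of indicators."""
        return len(self.indicators)

    @property
    def indicator_ids(self) -> list[str]:
        return [i.id for i in self.indicators]

    @property
    def dimension_ids(self) -> list[str]:
        return [d.id for d in self.dimensions]

    def indicator(self, indicator_id: str) -> IndicatorDef:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def members(self, dimension_id: str) -> list[str]:
        """Indicator ids belonging to one dimension, in schema order."""
        return [i.id for i in self.indicators if i.dimension == dimension_id]


@dataclass(frozen=True)
class RegionInfo:
    region: str
    category: Category


def schema_from_dict(payload: Mapping) -> IndicatorSchema:
    """Build a validated schema from a parsed YAML/JSON mapping."""
    try:
        dim_entries = list(payload["dimensions"])
        ind_entries = list(payload["indicators"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"schema must declare 'dimensions' and 'indicators': {exc}") from exc
    dimensions = tuple(
        Dimension(id=str(d["id"]), name=str(d.get("name", d["id"])), weight=d.get("weight"))
        for d in dim_entries
    )
    indicators = []
    for entry in ind_entries:
        raw_nature = entry.get("nature", "positive")
        try:
            nature = Nature(raw_nature)
        except ValueError as exc:
            raise SchemaError(
                f"indicator {entry.get('id')!r}: unknown nature {raw_nature!r} "
                f"(expected 'positive' or 'negative')"
            ) from exc
        indicators.append(
            IndicatorDef(
                id=str(entry["id"]),
                name=str(entry.get("name", entry["id"])),
                unit=str(entry.get("unit", "")),
                dimension=str(entry["dimension"]),
                nature=nature,
                weight=entry.get("weight"),
            )
        )
    return IndicatorSchema(dimensions=dimensions, indicators=tuple(indicators))


def read_schema(path: str | Path) -> IndicatorSchema:
    """Read and validate an indicator schema from YAML (or JSON)."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse schema {path}: {exc}") from exc
    if not isinstance(payload, Mapping):
        raise SchemaError(f"schema {path} does not contain a mapping")
    return schema_from_dict(payload)


@dataclass
class RawPanel:
    """Region x year x indicator table of raw values with region metadata.

    ``frame`` is tidy long form (``region, category, year, indicator,
    value``); missing observations are NaN rows, never absent rows, so the
    panel is always rectangular over its declared regions, years and
    indicators.
    """

    frame: pd.DataFrame
    regions: tuple[RegionInfo, ...] = field(default_factory=tuple)
    years: tuple[int, ...] = field(default_factory=tuple)
    indicators: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        """Number of evaluation objects (region-year pairs)."""
        return len(self.regions) * len(self.years)

    @property
    def categories(self) -> dict[str, Category]:
        return {r.region: r.category for r in self.regions}

    def wide(self) -> pd.DataFrame:
        """Pivot to (region, year) rows x indicator columns, schema order."""
        w = self.frame.pivot_table(
            index=["region", "year"], columns="indicator", values="value", dropna=False
        )
        return w.reindex(columns=list(self.indicators))

    def missing_cells(self) -> list[tuple[str, int, str]]:
        miss = self.frame[self.frame["value"].isna()]
        return list(miss[["region", "year", "indicator"]].itertuples(index=False, name=None))

    def value(self, region: str, year: int, indicator: str) -> float:
        sel = self.frame[
            (self.frame["region"] == region)
            & (self.frame["year"] == year)
            & (self.frame["indicator"] == indicator)
        ]
        if sel.empty:
            raise KeyError((region, year, indicator))
        return float(sel["value"].iloc[0])


def panel_from_frame(frame: pd.DataFrame, schema: IndicatorSchema) -> RawPanel:
    """Validate a tidy long frame against a schema and build a RawPanel.

    Region names are trimmed; categories are matched case-insensitively.
    The result is rectangularized: every (region, year, indicator) triple
    of the declared grid is present, absent observations as NaN.
    """
    missing_cols = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise PanelError(f"panel is missing columns {missing_cols}")
    frame = frame.loc[:, list(PANEL_COLUMNS)].copy()
    frame["region"] = frame["region"].astype(str).str.strip()
    frame["indicator"] = frame["indicator"].astype(str).str.strip()

    known = set(schema.indicator_ids)
    unknown = sorted(set(frame["indicator"]) - known)
    if unknown:
        raise PanelError(f"unknown indicator ids in panel: {unknown}")

    cat_raw = frame["category"].astype(str).str.strip().str.lower()
    valid = {c.value for c in Category}
    bad = frame.loc[~cat_raw.isin(valid)]
    if not bad.empty:
        row = bad.iloc[0]
        raise PanelError(
            f"unknown category {row['category']!r} for region {row['region']!r} "
            f"(row {bad.index[0]}); expected one of {sorted(valid)}"
        )
    frame["category"] = cat_raw

    try:
        frame["year"] = frame["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelError(f"non-integer year in panel: {exc}") from exc

    dup = frame.duplicated(subset=["region", "year", "indicator"], keep=False)
    if dup.any():
        first = frame.loc[dup].iloc[0]
        raise PanelError(
            "duplicate (region, year, indicator) rows, e.g. "
            f"({first['region']}, {first['year']}, {first['indicator']})"
        )

    cat_per_region = frame.groupby("region")["category"].nunique()
    inconsistent = cat_per_region[cat_per_region > 1]
    if not inconsistent.empty:
        raise PanelError(
            f"region(s) with conflicting categories: {list(inconsistent.index)}"
        )

    region_cat = frame.drop_duplicates("region").set_index("region")["category"]
    regions = tuple(
        RegionInfo(region=r, category=Category(region_cat[r])) for r in region_cat.index
    )
    years = tuple(sorted(frame["year"].unique()))
    indicators = tuple(i for i in schema.indicator_ids if i in set(frame["indicator"]))

    # Rectangularize so downstream interpolation sees explicit gaps.
    full = pd.MultiIndex.from_product(
        [[r.region for r in regions], years, indicators],
        names=["region", "year", "indicator"],
    )
    frame = (
        frame.set_index(["region", "year", "indicator"])
        .reindex(full)
        .reset_index()
    )
    frame["category"] = frame["region"].map({r.region: r.category.value for r in regions})
    frame["value"] = frame["value"].astype(float)
    frame = frame.loc[:, list(PANEL_COLUMNS)]
    return RawPanel(frame=frame, regions=regions, years=years, indicators=indicators)


def read_panel(path: str | Path, schema: IndicatorSchema) -> RawPanel:
    """Read a tidy long CSV panel and validate it against ``schema``."""
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    frame = pd.read_csv(path)
    return panel_from_frame(frame, schema)


def write_panel(panel: RawPanel, path: str | Path) -> None:
    """Write the documented CSV dialect; values at 12 significant digits."""
    out = panel.frame.copy()
    out["value"] = out["value"].map(lambda v: "" if pd.isna(v) else f"{v:.12g}")
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # "missing" | "negative" | "out-of-range"
    region: str
    year: int
    indicator: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]
    coverage: pd.Series  # indicator id -> observed fraction

    @property
    def ok(self) -> bool:
        return not self.issues


_NONNEGATIVE_UNIT_HINTS = ("piece", "number", "%", "yuan", "times")


def validate_panel(panel: RawPanel, schema: IndicatorSchema) -> ValidationReport:
    """Structural screening: missing cells, impossible values, coverage.

    Report-only — the panel is never modified. Percentage-unit indicators
    are range-checked against [0, 100]; count/amount units against >= 0.
    """
    issues: list[ValidationIssue] = []
    for region, year, indicator in panel.missing_cells():
        issues.append(
            ValidationIssue("missing", region, int(year), indicator, "value missing")
        )
    units = {i.id: i.unit for i in schema.indicators}
    observed = panel.frame.dropna(subset=["value"])
    for row in observed.itertuples(index=False):
        unit = units.get(row.indicator, "")
        low = unit.lower()
        if any(h in low for h in _NONNEGATIVE_UNIT_HINTS) and row.value < 0:
            issues.append(
                ValidationIssue(
                    "negative", row.region, int(row.year), row.indicator,
                    f"negative value {row.value} for unit {unit!r}",
                )
            )
        if unit.strip() == "%" and not (0.0 <= row.value <= 100.0):
            issues.append(
                ValidationIssue(
                    "out-of-range", row.region, int(row.year), row.indicator,
                    f"percentage {row.value} outside [0, 100]",
                )
            )
    counts = panel.frame.groupby("indicator")["value"].agg(["count", "size"])
    coverage = (counts["count"] / counts["size"]).reindex(list(panel.indicators))
    coverage.name = "coverage"
    return ValidationReport(issues=issues, coverage=coverage)


@dataclass
class ExpertScoreTable:
    """Expert x indicator importance scores on a 1-5 scale."""

    scores: pd.DataFrame  # index: expert id, columns: indicator id

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if np.isnan(vals).any():
            raise PanelError("expert score table has missing scores")
        if not np.all((vals >= 1) & (vals <= 5)):
            raise PanelError("expert scores must lie in 1..5")
        if not np.allclose(vals, np.round(vals)):
            raise PanelError("expert scores must be integers in 1..5")

    @property
    def experts(self) -> list[str]:
        return list(self.scores.index)


def read_expert_scores(path: str | Path, schema: IndicatorSchema | None = None) -> ExpertScoreTable:
    """Read long CSV (expert, indicator, score) into an ExpertScoreTable."""
    frame = pd.read_csv(path)
    needed = {"expert", "indicator", "score"}
    if not needed.issubset(frame.columns):
        raise PanelError(f"expert score file must have columns {sorted(needed)}")
    if schema is not None:
        unknown = sorted(set(frame["indicator"].astype(str)) - set(schema.indicator_ids))
        if unknown:
            raise PanelError(f"unknown indicator ids in expert scores: {unknown}")
    wide = frame.pivot_table(index="expert", columns="indicator", values="score")
    if schema is not None:
        wide = wide.reindex(columns=schema.indicator_ids)
    return ExpertScoreTable(scores=wide)


@dataclass
class VigilanceSeries:
    """Yearly national pharmacovigilance counts.

    Any column may be absent; per-year invariants (serious <= total
    reports, approvals <= applications) are enforced where both sides are
    present.
    """

    frame: pd.DataFrame  # index: year; columns subset of the four series

    SERIES = ("adr_reports", "serious_reports", "trial_applications", "trial_approvals")

    def __post_init__(self) -> None:
        f = self.frame
        extra = set(f.columns) - set(self.SERIES)
        if extra:
            raise PanelError(f"unknown vigilance series: {sorted(extra)}")
        for col in f.columns:
            vals = f[col].dropna()
            if (vals < 0).any():
                raise PanelError(f"negative count in series {col!r}")
        if {"adr_reports", "serious_reports"}.issubset(f.columns):
            both = f.dropna(subset=["adr_reports", "serious_reports"])
            bad = both[both["serious_reports"] > both["adr_reports"]]
            if not bad.empty:
                raise PanelError(
                    f"serious reports exceed total reports in year {bad.index[0]}"
                )
        if {"trial_applications", "trial_approvals"}.issubset(f.columns):
            both = f.dropna(subset=["trial_applications", "trial_approvals"])
            bad = both[both["trial_approvals"] > both["trial_applications"]]
            if not bad.empty:
                raise PanelError(
                    f"approvals exceed applications in year {bad.index[0]}"
                )

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.frame.index]


def read_vigilance(path: str | Path) -> VigilanceSeries:
    """Read a vigilance CSV with columns year + any of the four series."""
    frame = pd.read_csv(path)
    if "year" not in frame.columns:
        raise PanelError("vigilance file must have a 'year' column")
    frame = frame.set_index(frame["year"].astype(int)).drop(columns="year")
    return VigilanceSeries(frame=frame.sort_index())
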