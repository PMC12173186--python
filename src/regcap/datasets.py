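"""Loaders for the small reference datasets bundled with the package.

These are published summary tables for China's 31 provincial-level
regions: the two-level indicator weight system, the 2022 provincial
dimension/composite scores with economic-belt categories and ranks, and
national new-drug clinical-trial counts for 2020-2022. They let the whole
pipeline be exercised and cross-checked without any external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel_model import (
    Category,
    IndicatorSchema,
    VigilanceSeries,
    read_schema,
)

__all__ = [
    "load_indicator_schema",
    "load_provincial_scores_2022",
    "load_region_categories",
    "load_clinical_trials",
]

_DATA = resources.files("regcap.data")


def load_indicator_schema() -> IndicatorSchema:
    """The 5-dimension / 14-indicator schema with its frozen weight system."""
    with resources.as_file(_DATA / "indicator_schema.yaml") as p:
        return read_schema(p)


def load_provincial_scores_2022() -> pd.DataFrame:
    """2022 reference scores: 31 regions x (category, rank, composite, 5 dims)."""
    with (_DATA / "provincial_scores_2022.csv").open("rb") as fh:
        frame = pd.read_csv(fh)
    frame["category"] = frame["category"].map(Category)
    return frame


def load_region_categories() -> dict[str, Category]:
    """Economic-belt classification of the 31 provincial-level regions."""
    frame = load_provincial_scores_2022()
    return dict(zip(frame["region"], frame["category"]))


def load_clinical_trials() -> VigilanceSeries:
    """National new-drug clinical-trial applications and approvals, 2020-2022."""
    with (_DATA / "clinical_trials.csv").open("rb") as fh:
        frame = pd.read_csv(fh)
    return VigilanceSeries(frame=frame.set_index(frame["year"].astype(int)).drop(columns="year"))
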