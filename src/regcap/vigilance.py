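"""National pharmacovigilance descriptives.

Purely descriptive series: clinical-trial approval pass rates, the
share of serious reports among adverse-drug-reaction (ADR) reports, and
year-over-year changes. Printed rates round half-up at two decimals.
"""

from __future__ import annotations

import pandas as pd

from ._util import round_half_up
from .panel_model import VigilanceSeries

__all__ = ["pass_rate", "serious_proportion", "yoy_change", "vigilance_report"]


def pass_rate(approvals: int, applications: int) -> float:
    """Approvals / applications as a percentage, half-up at 2 decimals."""
    if applications <= 0:
        raise ValueError("applications must be positive")
    if approvals < 0 or approvals > applications:
        raise ValueError(f"approvals {approvals} outside [0, {applications}]")
    return round_half_up(approvals / applications * 100.0, 2)


def serious_proportion(series: VigilanceSeries) -> pd.Series:
    """Share of serious reports among ADR reports per year, percent."""
    f = series.frame
    if not {"adr_reports", "serious_reports"}.issubset(f.columns):
        raise ValueError("series lacks adr_reports/serious_reports columns")
    both = f.dropna(subset=["adr_reports", "serious_reports"])
    if (both["adr_reports"] <= 0).any():
        bad = both.index[both["adr_reports"] <= 0][0]
        raise ValueError(f"zero ADR report total in year {bad}")
    prop = both["serious_reports"] / both["adr_reports"] * 100.0
    prop = round_half_up(prop, 2)
    prop.name = "serious_proportion"
    return prop


def yoy_change(series: pd.Series) -> pd.Series:
    """Year-over-year percent change of a year-indexed series."""
    series = pd.Series(series, dtype=float).sort_index()
    if len(series) < 2:
        raise ValueError("need at least 2 years for year-over-year change")
    prev = series.shift(1)
    if (prev.iloc[1:] == 0).any():
        bad = prev.index[1:][prev.iloc[1:] == 0][0]
        raise ValueError(f"zero previous value before year {bad}")
    change = (series - prev) / prev * 100.0
    change = change.iloc[1:]
    change = round_half_up(change, 2)
    change.name = "yoy_change"
    return change


def vigilance_report(series: VigilanceSeries) -> pd.DataFrame:
    """Combined descriptive table: counts, pass rate, serious share, trends."""
    f = series.frame.copy()
    out = f.copy()
    if {"trial_applications", "trial_approvals"}.issubset(f.columns):
        both = f.dropna(subset=["trial_applications", "trial_approvals"])
        out.loc[both.index, "pass_rate"] = [
            pass_rate(int(a), int(q))
            for a, q in zip(both["trial_approvals"], both["trial_applications"])
        ]
    if {"adr_reports", "serious_reports"}.issubset(f.columns):
        out["serious_proportion"] = serious_proportion(series)
    for col in ("adr_reports", "serious_reports"):
        if col in f.columns and f[col].notna().sum() >= 2:
            out[f"{col}_yoy"] = yoy_change(f[col].dropna())
    out.index.name = "year"
    return out
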