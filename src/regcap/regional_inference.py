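"""One-way fixed-effects ANOVA across regional groups.

The classic decomposition: F = MSB / MSW with MSB = SSB / (k - 1) and
MSW = SSW / (N - k); the p-value is the upper tail of the F(k-1, N-k)
distribution. Significance stars follow the two-threshold convention
"*" p < 0.05, "**" p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnovaError

__all__ = ["AnovaResult", "one_way_anova", "significance_flags", "anova_table"]


@dataclass
class AnovaResult:
    group_stats: pd.DataFrame  # group, n, mean, sd
    F: float
    p: float
    df: tuple[int, int]  # (between, within)
    stars: str

    def formatted(self, decimals: int = 2) -> pd.Series:
        """Group summaries as 'mean ± sd' strings at printed precision."""
        return self.group_stats.apply(
            lambda r: f"{r['mean']:.{decimals}f} ± {r['sd']:.{decimals}f}", axis=1
        ).set_axis(self.group_stats["group"])


def significance_flags(p: float) -> str:
    """Star convention: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def one_way_anova(values: pd.Series, grouping: pd.Series) -> AnovaResult:
    """Fixed-effects one-way ANOVA of ``values`` over ``grouping`` labels.

    Requires >= 2 groups with >= 2 members each and positive pooled
    within-group variance; degenerate inputs raise :class:`AnovaError`.
    """
    values = pd.Series(values, dtype=float)
    grouping = pd.Series(grouping).reindex(values.index)
    if grouping.isna().any() or values.isna().any():
        raise AnovaError("missing values or group labels")
    groups = {g: v.to_numpy() for g, v in values.groupby(grouping, sort=False)}
    k = len(groups)
    if k < 2:
        raise AnovaError(f"need at least 2 groups, got {k}")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise AnovaError(f"group(s) with fewer than 2 members: {small}")
    n_total = int(values.size)
    grand = float(values.mean())
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    if ssw <= 0:
        raise AnovaError("degenerate ANOVA: zero within-group variance")
    msb, msw = ssb / df_b, ssw / df_w
    f_stat = msb / msw
    p = float(stats.f.sf(f_stat, df_b, df_w))
    group_stats = pd.DataFrame(
        {
            "group": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean": [float(v.mean()) for v in groups.values()],
            "sd": [float(np.std(v, ddof=1)) for v in groups.values()],
        }
    )
    return AnovaResult(
        group_stats=group_stats,
        F=float(f_stat),
        p=p,
        df=(df_b, df_w),
        stars=significance_flags(p),
    )


def anova_table(
    frame: pd.DataFrame,
    columns: list[str],
    grouping: str = "category",
) -> pd.DataFrame:
    """Run the ANOVA per score column; tidy table with F, p, stars, df."""
    records = []
    for col in columns:
        res = one_way_anova(frame[col], frame[grouping])
        rec = {"column": col, "F": res.F, "p": res.p, "stars": res.stars,
               "df_between": res.df[0], "df_within": res.df[1]}
        for _, row in res.group_stats.iterrows():
            rec[f"{row['group']}_mean"] = row["mean"]
            rec[f"{row['group']}_sd"] = row["sd"]
        records.append(rec)
    return pd.DataFrame.from_records(records)
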