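"""Subjective, entropy and combined indicator weights.

Three weight vectors are produced over the m indicators:

* subjective weights B_j — each expert's importance scores d_j (1-5
  scale) are turned into a proportion vector d_j / sum_j d_j; B is the
  unweighted mean of the per-expert vectors;
* entropy weights A_j — from the normalized panel, each indicator's
  share matrix P_ij = y_ij / sum_i y_ij gives an information entropy
  E_j = -(1/ln n) sum_i P_ij ln P_ij, and A_j = (1 - E_j) / (m - sum E);
  dispersed indicators (low entropy) carry more objective information
  and get more weight;
* combined weights W_j = A_j B_j / sum_j A_j B_j.

A :class:`WeightSet` additionally carries the two-level decomposition:
dimension weights W_d (sum of member W_j) and within-dimension weights
W_j / W_d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import WeightError
from .panel_model import ExpertScoreTable, IndicatorSchema
from .preprocessing import NormalizedPanel

__all__ = [
    "EntropyDetail",
    "WeightSet",
    "subjective_weights",
    "entropy_detail",
    "entropy_weights",
    "combine_weights",
    "build_weight_set",
    "compute_weights",
    "write_weights",
    "read_weights",
]


@dataclass
class EntropyDetail:
    """Per-object share matrix P_ij and per-indicator entropy E_j."""

    proportions: pd.DataFrame  # objects x indicators, columns sum to 1
    entropy: pd.Series  # indicator -> E_j in [0, 1]
    n: int  # number of evaluation objects in the slice


@dataclass
class WeightSet:
    """Indicator weights plus their two-level (dimension) decomposition.

    ``subjective`` and ``entropy`` are optional: a weight system frozen
    from a published table carries only the combined level.
    """

    combined: pd.Series
    dimension_weights: pd.Series
    within_dimension: pd.Series
    dimension_of: dict[str, str]
    subjective: pd.Series | None = None
    entropy: pd.Series | None = None

    def validate(self, atol: float = 1e-9) -> None:
        """Check the sum-to-one invariants at tolerance ``atol``.

        Frozen published weight systems are printed at 3 decimals and
        only satisfy the per-dimension sums to ~2e-3; pass a looser atol
        for those.
        """
        for name, vec in (
            ("combined", self.combined),
            ("dimension_weights", self.dimension_weights),
            ("subjective", self.subjective),
            ("entropy", self.entropy),
        ):
            if vec is None:
                continue
            if (vec < -atol).any():
                raise WeightError(f"{name} weights contain negative entries")
            if abs(vec.sum() - 1.0) > atol:
                raise WeightError(f"{name} weights sum to {vec.sum():.6f}, not 1")
        for dim in self.dimension_weights.index:
            members = [j for j, d in self.dimension_of.items() if d == dim]
            s = self.within_dimension[members].sum()
            if abs(s - 1.0) > atol:
                raise WeightError(
                    f"within-dimension weights of {dim!r} sum to {s:.6f}, not 1"
                )

    @classmethod
    def from_schema(cls, schema: IndicatorSchema) -> "WeightSet":
        """Build a frozen WeightSet from weights stored in the schema.

        Requires every dimension and indicator to carry a ``weight``
        field; the combined indicator weight is the product
        (dimension weight) x (within-dimension weight), renormalized to
        sum exactly to 1.
        """
        missing = [d.id for d in schema.dimensions if d.weight is None] + [
            i.id for i in schema.indicators if i.weight is None
        ]
        if missing:
            raise WeightError(f"schema has no frozen weights for: {missing}")
        dim_w = pd.Series({d.id: float(d.weight) for d in schema.dimensions})
        within = pd.Series({i.id: float(i.weight) for i in schema.indicators})
        dimension_of = {i.id: i.dimension for i in schema.indicators}
        combined = pd.Series(
            {j: dim_w[dimension_of[j]] * within[j] for j in schema.indicator_ids}
        )
        combined = combined / combined.sum()
        return cls(
            combined=combined,
            dimension_weights=dim_w,
            within_dimension=within,
            dimension_of=dimension_of,
        )


def subjective_weights(scores: ExpertScoreTable) -> pd.Series:
    """Importance-score proportion weights B_j, averaged over experts."""
    table = scores.scores.astype(float)
    per_expert = table.div(table.sum(axis=1), axis=0)
    b = per_expert.mean(axis=0)
    b.name = "subjective"
    return b


def entropy_detail(
    normalized: NormalizedPanel | pd.DataFrame,
    objects: list[tuple[str, int]] | None = None,
    epsilon: float = 0.0,
) -> EntropyDetail:
    """Share matrix and information entropy per indicator.

    ``normalized`` may be a NormalizedPanel or a plain objects-by-
    indicators frame of values in [0, 1]. ``objects`` restricts the
    slice (row labels). ``epsilon`` optionally shifts shares by a tiny
    constant before the log — a cross-checking alternative to the exact
    0*ln(0) := 0 convention used by default.
    """
    frame = normalized.values if isinstance(normalized, NormalizedPanel) else normalized
    if objects is not None:
        frame = frame.loc[objects]
    if frame.empty:
        raise WeightError("empty object slice for entropy computation")
    n = len(frame)
    col_sums = frame.sum(axis=0)
    zero_cols = col_sums[col_sums == 0].index
    if len(zero_cols):
        warnings.warn(
            f"all-zero normalized column(s) {list(zero_cols)}: entropy defined as 1",
            UserWarning,
            stacklevel=2,
        )
    p = frame.div(col_sums.replace(0.0, np.nan), axis=1)
    if epsilon:
        q = p + epsilon
        plogp = q * np.log(q)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = p * np.log(p)
        plogp = plogp.where(p > 0, 0.0)  # 0 * ln 0 := 0
    e = -plogp.sum(axis=0) / np.log(n) if n > 1 else pd.Series(1.0, index=frame.columns)
    e[zero_cols] = 1.0
    e = e.fillna(1.0).clip(0.0, 1.0)
    e.name = "entropy"
    p = p.fillna(0.0)
    return EntropyDetail(proportions=p, entropy=e, n=n)


def entropy_weights(detail: EntropyDetail, m: int | None = None) -> pd.Series:
    """Entropy weights A_j = (1 - E_j) / (m - sum_j E_j)."""
    e = detail.entropy
    m = len(e) if m is None else m
    if m < 2:
        raise WeightError("entropy weighting needs at least 2 indicators")
    denom = m - e.sum()
    if denom <= 0:
        raise WeightError(
            "no objective information: every indicator has entropy 1 "
            "(all columns constant)"
        )
    a = (1.0 - e) / denom
    a.name = "entropy_weight"
    return a


def combine_weights(a: pd.Series, b: pd.Series) -> pd.Series:
    """Combined weights W_j proportional to the product A_j * B_j."""
    if len(a) != len(b):
        raise WeightError("weight vectors have different lengths")
    b = b.reindex(a.index)
    prod = a * b
    total = prod.sum()
    if total <= 0:
        raise WeightError("all subjective-by-entropy weight products are zero")
    w = prod / total
    w.name = "combined"
    return w


def build_weight_set(
    w: pd.Series,
    schema: IndicatorSchema,
    subjective: pd.Series | None = None,
    entropy: pd.Series | None = None,
) -> WeightSet:
    """Decompose combined indicator weights into the two-level system."""
    w = w.reindex(schema.indicator_ids)
    dimension_of = {i.id: i.dimension for i in schema.indicators}
    dim_w = pd.Series(
        {d: w[schema.members(d)].sum() for d in schema.dimension_ids}, name="dimension"
    )
    zero = dim_w[dim_w == 0].index
    if len(zero):
        raise WeightError(f"dimension(s) with zero total weight: {list(zero)}")
    within = pd.Series(
        {j: w[j] / dim_w[dimension_of[j]] for j in schema.indicator_ids}, name="within"
    )
    return WeightSet(
        combined=w,
        dimension_weights=dim_w,
        within_dimension=within,
        dimension_of=dimension_of,
        subjective=subjective,
        entropy=entropy,
    )


def compute_weights(
    normalized: NormalizedPanel,
    expert_scores: ExpertScoreTable,
    schema: IndicatorSchema,
    epsilon: float = 0.0,
) -> WeightSet:
    """Full weighting stage: subjective + entropy -> combined WeightSet.

    Entropy is computed once over all objects of ``normalized`` (the
    pooled panel) and the resulting weight system is held fixed across
    years.
    """
    b = subjective_weights(expert_scores).reindex(schema.indicator_ids)
    detail = entropy_detail(normalized, epsilon=epsilon)
    a = entropy_weights(detail, schema.m).reindex(schema.indicator_ids)
    w = combine_weights(a, b)
    ws = build_weight_set(w, schema, subjective=b, entropy=a)
    ws.validate(atol=1e-9)
    return ws


def write_weights(weights: WeightSet, path) -> None:
    """Persist all weight vectors as YAML at 6 decimals."""

    def _ser(vec: pd.Series | None):
        if vec is None:
            return None
        return {str(k): round(float(v), 6) for k, v in vec.items()}

    payload = {
        "combined": _ser(weights.combined),
        "dimension_weights": _ser(weights.dimension_weights),
        "within_dimension": _ser(weights.within_dimension),
        "subjective": _ser(weights.subjective),
        "entropy": _ser(weights.entropy),
        "dimension_of": dict(weights.dimension_of),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_weights(path) -> WeightSet:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)

    def _de(d):
        return None if d is None else pd.Series(d, dtype=float)

    return WeightSet(
        combined=_de(payload["combined"]),
        dimension_weights=_de(payload["dimension_weights"]),
        within_dimension=_de(payload["within_dimension"]),
        dimension_of=dict(payload["dimension_of"]),
        subjective=_de(payload.get("subjective")),
        entropy=_de(payload.get("entropy")),
    )
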