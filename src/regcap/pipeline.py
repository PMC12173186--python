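"""End-to-end orchestration: raw panel -> normalized -> weights -> scores
-> regional ANOVA -> obstacle diagnosis -> summary bundle.

``run_pipeline`` is deterministic given identical inputs: outputs use
stable key ordering and 6-decimal floats, and the run log records a
SHA-256 hash of every file written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import RegcapError
from .obstacle_diagnosis import obstacle_degrees, regional_obstacle_summary, top_obstacles
from .panel_model import (
    IndicatorSchema,
    read_expert_scores,
    read_panel,
    read_schema,
    read_vigilance,
)
from .preprocessing import interpolate_missing, normalize_panel
from .regional_inference import anova_table
from .scoring import count_above_mean, group_means, score_panel, trend_table
from .vigilance import vigilance_report
from .weighting import WeightSet, compute_weights, read_weights, write_weights

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """File-level configuration of one pipeline run."""

    schema: Path
    panel: Path
    out_dir: Path
    expert_scores: Path | None = None
    frozen_weights: Path | None = None
    vigilance: Path | None = None
    scope: str = "pooled"
    top_k: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        self.schema = Path(self.schema)
        self.panel = Path(self.panel)
        self.out_dir = Path(self.out_dir)
        if (self.expert_scores is None) == (self.frozen_weights is None):
            raise RegcapError(
                "exactly one of expert_scores / frozen_weights must be given"
            )
        for name in ("schema", "panel", "expert_scores", "frozen_weights", "vigilance"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def _p(key):
            v = payload.get(key)
            return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

        return cls(
            schema=_p("schema"),
            panel=_p("panel"),
            out_dir=_p("out_dir") or base / "out",
            expert_scores=_p("expert_scores"),
            frozen_weights=_p("frozen_weights"),
            vigilance=_p("vigilance"),
            scope=payload.get("scope", "pooled"),
            top_k=int(payload.get("top_k", 2)),
            seed=payload.get("seed"),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a mapping of artifact name -> written path. Stage failures
    propagate as the stage's own exception, prefixed with the stage name
    by the CLI wrapper.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    schema = read_schema(config.schema)
    panel = read_panel(config.panel, schema)
    panel, imputed = interpolate_missing(panel)
    normalized = normalize_panel(panel, schema, scope=config.scope)

    norm_path = out / "normalized.csv"
    normalized.to_long().to_csv(norm_path, index=False)
    written["normalized"] = norm_path

    if config.expert_scores is not None:
        experts = read_expert_scores(config.expert_scores, schema)
        weights = compute_weights(normalized, experts, schema)
        weights.validate(atol=1e-9)
    else:
        weights = read_weights(config.frozen_weights)
        weights.validate(atol=5e-3)
    weights_path = out / "weights.yaml"
    write_weights(weights, weights_path)
    written["weights"] = weights_path

    scores = score_panel(normalized, weights, schema)
    scores_path = out / "scores.csv"
    scores.frame.to_csv(scores_path, index=False, float_format="%.6f")
    written["scores"] = scores_path

    last_year = max(panel.years)
    anova = anova_table(scores.year_slice(last_year), scores.score_columns)
    anova_path = out / "anova.csv"
    anova.to_csv(anova_path, index=False, float_format="%.6f")
    written["anova"] = anova_path

    report = obstacle_degrees(normalized, weights)
    summary_deg = regional_obstacle_summary(report, {r.region: r.category for r in panel.regions})
    obstacle_rows = []
    for (category, year), row in summary_deg.iterrows():
        for rank, (ind, deg) in enumerate(top_obstacles(row, config.top_k), start=1):
            obstacle_rows.append(
                {"category": category, "year": int(year), "rank": rank,
                 "indicator": ind, "degree_pct": deg}
            )
    obstacles_path = out / "obstacles.csv"
    pd.DataFrame(obstacle_rows).to_csv(obstacles_path, index=False, float_format="%.6f")
    written["obstacles"] = obstacles_path

    if config.vigilance is not None:
        vig = read_vigilance(config.vigilance)
        vig_path = out / "vigilance_report.csv"
        vigilance_report(vig).to_csv(vig_path, float_format="%.6f")
        written["vigilance"] = vig_path

    last = scores.year_slice(last_year)
    gm = group_means(last, scores.score_columns)
    national = group_means(last, scores.score_columns, grouping="national")
    trends = trend_table(scores)
    summary = {
        "last_year": int(last_year),
        "n_regions": len(panel.regions),
        "n_years": len(panel.years),
        "imputed_cells": len(imputed),
        "above_average_count": count_above_mean(last["composite"], decimals=3),
        "group_means": gm.to_dict(orient="records"),
        "national_means": national.to_dict(orient="records"),
        "trend_table": trends.where(trends.notna(), None).to_dict(orient="records"),
        "normalization_scope": normalized.scope,
        "seed": config.seed,
        "version": __version__,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True), encoding="utf-8"
    )
    written["summary"] = summary_path

    log = {
        "version": __version__,
        "scope": normalized.scope,
        "seed": config.seed,
        "inputs": {k: str(getattr(config, k)) for k in
                   ("schema", "panel", "expert_scores", "frozen_weights", "vigilance")},
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in written.items()},
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True), encoding="utf-8")
    written["run_log"] = log_path
    return written
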