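"""Synthetic provincial panels, expert scores and vigilance series.

The generator emulates the structure of the real study inputs — 31
provincial-level regions in three economic belts (12 eastern, 9 central,
10 western), 14 indicators observed 2018-2022, 7 experts scoring
importance on a 1-5 scale — with a documented latent model:

    z[r, t, j] = latent(category) + u_r + trend * (t - t0) + eps

where u_r ~ N(0, noise_sd^2) is a stable region effect and
eps ~ N(0, noise_sd^2) is observation noise. Each indicator maps z
through a monotone unit-appropriate link (qualified-rate percentages
land in [85, 100], counts become nonnegative integers on an exponential
scale, monetary amounts stay positive). Because every link is monotone
increasing, latent capacity ordering is preserved in expectation, which
is what the parameter-recovery tests exploit.

All randomness flows from the single ``seed`` through one
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .panel_model import (
    Category,
    ExpertScoreTable,
    IndicatorSchema,
    RawPanel,
    VigilanceSeries,
    panel_from_frame,
)

__all__ = ["SimConfig", "simulate_panel", "simulate_expert_scores", "simulate_vigilance"]

_CATEGORIES = (Category.EASTERN, Category.CENTRAL, Category.WESTERN)


@dataclass
class SimConfig:
    """Study-shaped simulation settings.

    ``category_gap`` is the latent advantage of the eastern over the
    western belt (the central belt sits midway); explicit
    ``latent_by_category`` overrides it. ``noise_sd`` controls both the
    stable region effect and the per-observation noise.
    """

    seed: int
    n_regions: tuple[int, int, int] = (12, 9, 10)  # eastern, central, western
    years: tuple[int, ...] = (2018, 2019, 2020, 2021, 2022)
    latent_by_category: tuple[float, float, float] | None = None
    category_gap: float = 0.2
    noise_sd: float = 0.1
    trend: float = 0.02
    missing_rate: float = 0.02
    n_experts: int = 7
    expert_disagreement: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory for reproducibility")
        if any(n < 1 for n in self.n_regions):
            raise SimulationError("each category needs at least one region")
        if len(self.years) < 1:
            raise SimulationError("need at least one year")
        if self.category_gap < 0:
            raise SimulationError("category_gap must be >= 0")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must lie in [0, 1)")
        if self.n_experts < 1:
            raise SimulationError("need at least one expert")

    @property
    def latents(self) -> tuple[float, float, float]:
        if self.latent_by_category is not None:
            return self.latent_by_category
        base = 0.45
        return (base + self.category_gap, base + self.category_gap / 2.0, base)

    def region_names(self) -> list[tuple[str, Category]]:
        prefixes = ("E", "C", "W")
        out = []
        for prefix, cat, n in zip(prefixes, _CATEGORIES, self.n_regions):
            out.extend((f"{prefix}{i + 1:02d}", cat) for i in range(n))
        return out


def _link(indicator, z: np.ndarray) -> np.ndarray:
    """Map latent capacity to a plausible raw scale for the indicator's unit."""
    unit = indicator.unit.strip().lower()
    name = indicator.name.lower()
    if unit == "%":
        if "qualified" in name or "rate" in name:
            return 85.0 + 15.0 * np.clip(z, 0.0, 1.0)
        return 100.0 * np.clip(z, 0.0, 1.0)
    if "piece" in unit or "number" in unit or "times" in unit:
        return np.rint(10.0 * np.exp(3.0 + 2.0 * z)).clip(min=0.0)
    if "yuan" in unit:
        return 12.0 * np.clip(z, 0.0, None)
    # dimensionless index
    return np.clip(z, 0.0, 1.0)


def simulate_panel(
    config: SimConfig, schema: IndicatorSchema
) -> tuple[RawPanel, pd.DataFrame]:
    """Draw a raw panel plus the latent truth table used to generate it.

    Returns ``(panel, truth)`` where ``truth`` has one row per region
    with its category and latent capacity (category latent + region
    effect) — the quantity recovery tests correlate composite scores
    against.
    """
    rng = np.random.default_rng(config.seed)
    regions = config.region_names()
    latents = dict(zip(_CATEGORIES, config.latents))
    year0 = config.years[0]

    rows = []
    truth_rows = []
    for region, cat in regions:
        u = rng.normal(0.0, config.noise_sd)
        capacity = latents[cat] + u
        truth_rows.append({"region": region, "category": cat.value, "latent": capacity})
        for year in config.years:
            drift = config.trend * (year - year0)
            for ind in schema.indicators:
                z = capacity + drift + rng.normal(0.0, config.noise_sd)
                value = float(_link(ind, np.asarray(z)))
                rows.append(
                    {
                        "region": region,
                        "category": cat.value,
                        "year": int(year),
                        "indicator": ind.id,
                        "value": value,
                    }
                )
    frame = pd.DataFrame(rows)

    if config.missing_rate > 0:
        mask = rng.random(len(frame)) < config.missing_rate
        # Keep at least one observation per (region, indicator) series.
        frame["_mask"] = mask
        for (_, _), grp in frame.groupby(["region", "indicator"], sort=False):
            if grp["_mask"].all():
                keep = rng.choice(grp.index)
                frame.loc[keep, "_mask"] = False
        frame.loc[frame["_mask"], "value"] = np.nan
        frame = frame.drop(columns="_mask")

    panel = panel_from_frame(frame, schema)
    truth = pd.DataFrame(truth_rows).set_index("region")
    return panel, truth


def simulate_expert_scores(config: SimConfig, schema: IndicatorSchema) -> ExpertScoreTable:
    """Integer 1-5 importance scores around a per-indicator consensus."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = schema.m
    consensus = rng.integers(2, 6, size=m).astype(float)  # consensus in 2..5
    jitter = rng.normal(0.0, config.expert_disagreement, size=(config.n_experts, m))
    scores = np.clip(np.rint(consensus[None, :] + jitter), 1, 5).astype(int)
    table = pd.DataFrame(
        scores,
        index=[f"expert_{i + 1}" for i in range(config.n_experts)],
        columns=schema.indicator_ids,
    )
    return ExpertScoreTable(scores=table)


def simulate_vigilance(config: SimConfig, noise: float | None = None) -> VigilanceSeries:
    """Yearly national counts with rising totals and a rising serious share.

    ``noise`` defaults to ``config.noise_sd``; at zero the totals are
    exactly monotone increasing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    noise = config.noise_sd if noise is None else noise
    years = list(config.years)
    t = np.arange(len(years))
    adr = np.rint(1.5e6 * np.exp(0.08 * t + rng.normal(0.0, 0.05 * noise, len(t)))).astype(int)
    share = 0.08 + 0.01 * t  # rising serious share
    serious = np.minimum(np.rint(adr * share), adr).astype(int)
    applications = np.rint(1100 * np.exp(0.15 * t + rng.normal(0.0, 0.1 * noise, len(t)))).astype(int)
    rate = np.clip(0.78 + 0.02 * t + rng.normal(0.0, 0.02 * noise, len(t)), 0.0, 1.0)
    approvals = np.minimum(np.rint(applications * rate), applications).astype(int)
    frame = pd.DataFrame(
        {
            "adr_reports": adr,
            "serious_reports": serious,
            "trial_applications": applications,
            "trial_approvals": approvals,
        },
        index=pd.Index(years, name="year"),
    )
    return VigilanceSeries(frame=frame)
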