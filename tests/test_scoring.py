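"""Dimension scores, composite index, ranking and descriptives."""

import numpy as np
import pandas as pd
import pytest

import regcap as rc
from regcap._util import round_half_up


class TestCompositeArithmetic:
    def test_dimension_score_is_weighted_mean(self, tiny_schema):
        w = pd.Series({"a": 0.25, "b": 0.25, "c": 0.5})
        ws = rc.build_weight_set(w, tiny_schema)
        values = pd.DataFrame(
            {"a": [1.0], "b": [0.0], "c": [1.0]},
            index=pd.MultiIndex.from_tuples([("R1", 2020)], names=["region", "year"]),
        )
        norm = _norm(values)
        dims = rc.dimension_scores(norm, ws, tiny_schema)
        assert dims.loc[("R1", 2020), "d1"] == pytest.approx(0.5)
        assert dims.loc[("R1", 2020), "d2"] == pytest.approx(1.0)

    def test_all_ones_profile_scores_one_everywhere(self, schema, frozen_weights):
        idx = pd.MultiIndex.from_tuples([("R1", 2022)], names=["region", "year"])
        values = pd.DataFrame(1.0, index=idx, columns=schema.indicator_ids)
        dims = rc.dimension_scores(_norm(values), frozen_weights, schema)
        # printed within-dimension weights sum to 1 within 2e-3
        assert np.allclose(dims.to_numpy(), 1.0, atol=2e-3)

    @pytest.mark.parametrize(
        "region,expected",
        [("Beijing", 0.172), ("Jiangsu", 0.204), ("Xinjiang", 0.038)],
    )
    def test_reference_composites_reconstruct(self, ref_scores, frozen_weights,
                                              schema, region, expected):
        row = ref_scores.set_index("region").loc[region, schema.dimension_ids]
        comp = float((frozen_weights.dimension_weights * row.astype(float)).sum())
        assert round_half_up(comp, 3) == expected

    def test_zero_dimensions_give_zero_composite(self, tiny_schema):
        ws = rc.build_weight_set(pd.Series({"a": 0.3, "b": 0.3, "c": 0.4}), tiny_schema)
        dims = pd.DataFrame({"d1": [0.0], "d2": [0.0]})
        assert rc.composite_scores(dims, ws).iloc[0] == 0.0

    def test_composite_monotone_in_each_normalized_value(self, tiny_schema):
        rng = np.random.default_rng(5)
        w = pd.Series(rng.dirichlet(np.ones(3)), index=["a", "b", "c"])
        ws = rc.build_weight_set(w, tiny_schema)
        idx = pd.MultiIndex.from_tuples([("R1", 2020)], names=["region", "year"])
        base_vals = rng.uniform(0.1, 0.8, 3)
        base = pd.DataFrame([base_vals], index=idx, columns=["a", "b", "c"])
        comp0 = _composite(base, ws, tiny_schema)
        for col in ("a", "b", "c"):
            bumped = base.copy()
            bumped[col] += 0.1
            assert _composite(bumped, ws, tiny_schema) >= comp0

    def test_composite_invariant_under_indicator_permutation(self, tiny_schema):
        w = pd.Series({"a": 0.2, "b": 0.3, "c": 0.5})
        ws = rc.build_weight_set(w, tiny_schema)
        idx = pd.MultiIndex.from_tuples([("R1", 2020)], names=["region", "year"])
        vals = pd.DataFrame([[0.4, 0.7, 0.1]], index=idx, columns=["a", "b", "c"])
        shuffled = vals[["c", "a", "b"]]
        assert _composite(vals, ws, tiny_schema) == pytest.approx(
            _composite(shuffled, ws, tiny_schema)
        )


class TestRanking:
    def test_reference_tie_pattern_one_two_two_four(self):
        comp = pd.Series({"Jiangsu": 0.204, "Beijing": 0.172, "Zhejiang": 0.172,
                          "Shanghai": 0.162})
        ranks = rc.rank_regions(comp)
        assert ranks.to_dict() == {"Jiangsu": 1, "Beijing": 2, "Zhejiang": 2,
                                   "Shanghai": 4}

    def test_distinct_values_rank_descending(self):
        ranks = rc.rank_regions(pd.Series({"x": 3.0, "y": 2.0, "z": 1.0}))
        assert list(ranks) == [1, 2, 3]

    def test_all_equal_all_rank_one(self):
        ranks = rc.rank_regions(pd.Series({"x": 1.0, "y": 1.0}))
        assert list(ranks) == [1, 1]

    def test_full_reference_rank_column_reproduced(self, ref_scores):
        ranks = rc.rank_regions(ref_scores.set_index("region")["composite"])
        assert (ranks == ref_scores.set_index("region")["rank"]).all()


class TestCountAboveMean:
    def test_simple_vector(self):
        assert rc.count_above_mean([1, 2, 3]) == 1

    def test_all_equal_counts_zero(self):
        assert rc.count_above_mean([2, 2, 2]) == 0

    def test_reference_composites_at_printed_precision(self, ref_scores):
        assert rc.count_above_mean(ref_scores["composite"], decimals=3) == 13


class TestGroupDescriptives:
    def test_national_and_western_means(self, ref_scores):
        nat = rc.group_means(ref_scores, ["composite"], grouping="national")
        assert round_half_up(nat.loc[0, "mean"], 3) == 0.113
        gm = rc.group_means(ref_scores.assign(category=ref_scores["category"].map(lambda c: c.value)),
                            ["composite"])
        west = gm[gm["group"] == "western"].iloc[0]
        assert round_half_up(west["mean"], 3) == 0.092
        assert west["n"] == 10

    def test_singleton_group_sd_reported_zero_and_flagged(self):
        frame = pd.DataFrame({"category": ["a"], "v": [3.0]})
        gm = rc.group_means(frame, ["v"])
        assert gm.loc[0, "sd"] == 0.0
        assert not gm.loc[0, "sd_defined"]

    def test_sample_sd_uses_n_minus_one(self):
        frame = pd.DataFrame({"category": ["g"] * 3, "v": [1.0, 2.0, 3.0]})
        gm = rc.group_means(frame, ["v"])
        assert gm.loc[0, "sd"] == pytest.approx(1.0)


class TestTrendTable:
    def test_two_year_delta(self, tiny_schema):
        table = _score_table(tiny_schema, {2018: 0.10, 2019: 0.12})
        trends = rc.trend_table(table, include_national=False)
        comp = trends[trends["column"] == "composite"].sort_values("year")
        assert np.isnan(comp["delta"].iloc[0])
        assert comp["delta"].iloc[1] == pytest.approx(0.02)

    def test_constant_series_all_zero_deltas(self, tiny_schema):
        table = _score_table(tiny_schema, {2018: 0.1, 2019: 0.1, 2020: 0.1})
        trends = rc.trend_table(table, include_national=False)
        comp = trends[trends["column"] == "composite"]
        assert np.allclose(comp["delta"].dropna(), 0.0)

    def test_upward_drift_gives_positive_deltas(self, schema):
        cfg = rc.SimConfig(seed=9, noise_sd=0.0, trend=0.03, missing_rate=0.0)
        panel, _ = rc.simulate_panel(cfg, schema)
        norm = rc.normalize_panel(panel, schema)
        experts = rc.simulate_expert_scores(cfg, schema)
        ws = rc.compute_weights(norm, experts, schema)
        table = rc.score_panel(norm, ws, schema)
        trends = rc.trend_table(table)
        comp = trends[trends["column"] == "composite"]
        assert (comp["delta"].dropna() > 0).all()


def _norm(values: pd.DataFrame) -> rc.NormalizedPanel:
    cats = {r: rc.Category.EASTERN for r in values.index.get_level_values(0)}
    bounds = pd.DataFrame({"x_min": 0.0, "x_max": 1.0}, index=values.columns)
    return rc.NormalizedPanel(values=values, bounds=bounds, scope="pooled",
                              categories=cats)


def _composite(values, ws, schema) -> float:
    dims = rc.dimension_scores(_norm(values), ws, schema)
    return float(rc.composite_scores(dims, ws).iloc[0])


def _score_table(schema, composites_by_year):
    rows = []
    for year, comp in composites_by_year.items():
        rows.append({"region": "R1", "category": "eastern", "year": year,
                     "d1": comp, "d2": comp, "composite": comp, "rank": 1})
    return rc.ScoreTable(frame=pd.DataFrame(rows), dimension_columns=["d1", "d2"])
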