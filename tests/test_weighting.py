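"""Subjective, entropy and combined weighting.

Hand-computed oracle values are frozen in the assertions; the entropy
implementation is additionally cross-checked against a brute-force
direct-summation oracle on random panels.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regcap as rc
from regcap.errors import WeightError
from regcap.weighting import entropy_detail, entropy_weights


def expert_table(*rows, indicators=None):
    indicators = indicators or [f"i{k}" for k in range(len(rows[0]))]
    return rc.ExpertScoreTable(
        scores=pd.DataFrame(list(rows), columns=indicators,
                            index=[f"e{k}" for k in range(len(rows))])
    )


def brute_force_entropy(matrix: np.ndarray) -> np.ndarray:
    """Direct elementwise summation of the entropy definition."""
    n, m = matrix.shape
    e = np.zeros(m)
    for j in range(m):
        total = matrix[:, j].sum()
        s = 0.0
        for i in range(n):
            p = matrix[i, j] / total
            if p > 0:
                s += p * np.log(p)
        e[j] = -s / np.log(n)
    return e


class TestSubjectiveWeights:
    def test_single_expert_proportions(self):
        b = rc.subjective_weights(expert_table([5, 4, 1]))
        assert list(b) == pytest.approx([0.5, 0.4, 0.1])

    def test_equal_scores_give_uniform_weights(self):
        b = rc.subjective_weights(expert_table([3, 3, 3, 3]))
        assert list(b) == pytest.approx([0.25] * 4)

    def test_two_experts_mean_of_proportion_vectors(self):
        # per-expert (2/3, 1/3) and (1/3, 2/3) -> mean (0.5, 0.5), which
        # differs from proportions of summed scores only in general; here
        # the symmetric case pins the per-expert convention exactly.
        b = rc.subjective_weights(expert_table([4, 2], [2, 4]))
        assert list(b) == pytest.approx([0.5, 0.5])

    def test_asymmetric_two_experts(self):
        # e1: (5/9, 4/9); e2: (1/6, 5/6); mean = (0.3611..., 0.6388...)
        b = rc.subjective_weights(expert_table([5, 4], [1, 5]))
        assert list(b) == pytest.approx([(5 / 9 + 1 / 6) / 2, (4 / 9 + 5 / 6) / 2])

    @given(
        st.lists(
            st.lists(st.integers(1, 5), min_size=3, max_size=3),
            min_size=1, max_size=7,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_weights_sum_to_one_and_are_nonnegative(self, rows):
        b = rc.subjective_weights(expert_table(*rows))
        assert b.sum() == pytest.approx(1.0, abs=1e-9)
        assert (b >= 0).all()


class TestEntropy:
    def test_degenerate_distribution_has_zero_entropy(self):
        frame = pd.DataFrame({"j": [0.0, 1.0]})
        detail = entropy_detail(frame)
        assert detail.entropy["j"] == pytest.approx(0.0, abs=1e-12)
        assert list(detail.proportions["j"]) == pytest.approx([0.0, 1.0])

    def test_uniform_column_has_unit_entropy(self):
        frame = pd.DataFrame({"j": [0.4, 0.4]})
        detail = entropy_detail(frame)
        assert detail.entropy["j"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_value_column(self):
        # p = (1/6, 1/3, 1/2); -sum p ln p = 1.011404; / ln 3 = 0.920620
        frame = pd.DataFrame({"j": [1.0, 2.0, 3.0]})
        detail = entropy_detail(frame)
        assert detail.entropy["j"] == pytest.approx(0.9206198357143052, abs=1e-9)

    def test_all_zero_column_entropy_one_with_warning(self):
        frame = pd.DataFrame({"j": [0.0, 0.0], "k": [0.0, 1.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            detail = entropy_detail(frame)
        assert detail.entropy["j"] == 1.0

    def test_matches_brute_force_oracle_on_random_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mat = rng.uniform(0.01, 1.0, size=(10, 6))
            frame = pd.DataFrame(mat, columns=[f"j{k}" for k in range(6)])
            detail = entropy_detail(frame)
            assert np.allclose(detail.entropy.to_numpy(), brute_force_entropy(mat),
                               atol=1e-12)

    def test_proportions_sum_to_one_per_indicator(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.uniform(0, 1, (8, 4)))
        detail = entropy_detail(frame)
        assert np.allclose(detail.proportions.sum(axis=0), 1.0, atol=1e-12)


class TestEntropyWeights:
    def test_zero_entropy_takes_all_weight(self):
        a = entropy_weights_from([1.0, 0.0])
        assert list(a) == pytest.approx([0.0, 1.0])

    def test_symmetric_entropies_share_equally(self):
        a = entropy_weights_from([0.5, 0.5])
        assert list(a) == pytest.approx([0.5, 0.5])

    def test_derived_pair(self):
        a = entropy_weights_from([0.9206198357143052, 1.0])
        assert list(a) == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_all_constant_indicators_error(self):
        with pytest.raises(WeightError, match="no objective information"):
            entropy_weights_from([1.0, 1.0])


def entropy_weights_from(entropies):
    detail = rc.EntropyDetail(
        proportions=pd.DataFrame(),
        entropy=pd.Series(entropies, index=[f"j{k}" for k in range(len(entropies))]),
        n=2,
    )
    return entropy_weights(detail)


class TestCombineWeights:
    def test_uniform_entropy_returns_subjective(self):
        a = pd.Series([0.5, 0.5], index=["x", "y"])
        b = pd.Series([0.8, 0.2], index=["x", "y"])
        assert list(rc.combine_weights(a, b)) == pytest.approx([0.8, 0.2])

    def test_hand_computed_products(self):
        a = pd.Series([0.3, 0.7], index=["x", "y"])
        b = pd.Series([0.6, 0.4], index=["x", "y"])
        w = rc.combine_weights(a, b)
        assert list(w) == pytest.approx([0.18 / 0.46, 0.28 / 0.46])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=50, derandomize=True)
    def test_commutative_and_normalized(self, raw_a, data):
        raw_b = data.draw(
            st.lists(st.floats(0.01, 1.0), min_size=len(raw_a), max_size=len(raw_a))
        )
        idx = [f"j{k}" for k in range(len(raw_a))]
        a = pd.Series(raw_a, index=idx)
        a = a / a.sum()
        b = pd.Series(raw_b, index=idx)
        b = b / b.sum()
        w_ab = rc.combine_weights(a, b)
        w_ba = rc.combine_weights(b, a)
        assert np.allclose(w_ab, w_ba, atol=1e-12)
        assert w_ab.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_products_error(self):
        a = pd.Series([0.0, 1.0], index=["x", "y"])
        b = pd.Series([1.0, 0.0], index=["x", "y"])
        with pytest.raises(WeightError):
            rc.combine_weights(a, b)


class TestWeightSet:
    def test_two_dimension_decomposition(self, tiny_schema):
        w = pd.Series({"a": 0.1, "b": 0.2, "c": 0.7})
        ws = rc.build_weight_set(w, tiny_schema)
        assert ws.dimension_weights["d1"] == pytest.approx(0.3)
        assert ws.dimension_weights["d2"] == pytest.approx(0.7)
        assert ws.within_dimension["a"] == pytest.approx(1 / 3)
        assert ws.within_dimension["c"] == pytest.approx(1.0)
        # identity: dimension weight x within weight reproduces W_j
        for j in w.index:
            assert ws.dimension_weights[ws.dimension_of[j]] * ws.within_dimension[j] == (
                pytest.approx(w[j])
            )

    def test_zero_weight_dimension_is_an_error(self, tiny_schema):
        w = pd.Series({"a": 0.0, "b": 0.0, "c": 1.0})
        with pytest.raises(WeightError, match="d1"):
            rc.build_weight_set(w, tiny_schema)

    def test_bundled_weight_system_dimension_weights(self, schema, frozen_weights):
        expected = {"resource_acquisition": 0.153, "functional_performance": 0.218,
                    "performance_level": 0.289, "learning_development": 0.210,
                    "internet_application": 0.130}
        for dim, val in expected.items():
            assert frozen_weights.dimension_weights[dim] == pytest.approx(val)
        # within-dimension vectors each sum to 1 within printed precision
        for dim in schema.dimension_ids:
            s = frozen_weights.within_dimension[schema.members(dim)].sum()
            assert s == pytest.approx(1.0, abs=2e-3)
        frozen_weights.validate(atol=5e-3)

    def test_constant_indicator_chains_to_zero_combined_weight(self, panel_factory):
        from test_preprocessing import panel_schema

        panel = panel_factory(
            {"R1": {"a": [1.0], "b": [5], "c": [2.0]},
             "R2": {"a": [2.0], "b": [5], "c": [3.0]},
             "R3": {"a": [3.0], "b": [5], "c": [4.0]}},
        )
        schema = panel_schema(panel)
        with pytest.warns(UserWarning):
            norm = rc.normalize_panel(panel, schema)
        experts = expert_table([5, 5, 5], indicators=["a", "b", "c"])
        ws = rc.compute_weights(norm, experts, schema)
        assert ws.entropy["b"] == pytest.approx(0.0, abs=1e-12)
        assert ws.combined["b"] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_yaml(self, tmp_path, tiny_schema):
        w = pd.Series({"a": 0.1, "b": 0.2, "c": 0.7})
        ws = rc.build_weight_set(w, tiny_schema)
        path = tmp_path / "w.yaml"
        from regcap.weighting import read_weights, write_weights

        write_weights(ws, path)
        again = read_weights(path)
        assert np.allclose(again.combined[w.index], w, atol=1e-6)
        assert again.dimension_of == ws.dimension_of
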