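"""Differential expression, gene scoring, metabolome classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from contextgem.omics import (
    ExpressionTable,
    MetabolomeTable,
    OmicsValidationError,
    classify_detection,
    differential_expression,
    metabolite_fold_changes,
    production_targets,
    rank_gene_scores,
)

from conftest import build_model


def make_expr(rows: dict[str, list[float]]) -> ExpressionTable:
    values = pd.DataFrame(rows, index=["A_1", "A_2", "B_1", "B_2"]).T
    return ExpressionTable(values=values, groups={"A_1": "A", "A_2": "A",
                                                  "B_1": "B", "B_2": "B"})


class TestDifferentialExpression:
    def test_planted_two_fold_called_up(self):
        table = differential_expression(
            make_expr({"g": [200, 202, 100, 101]}), "A", "B"
        )
        assert table.loc["g", "fold_change"] == pytest.approx(2.0, rel=0.02)
        assert table.loc["g", "call"] == "up"

    def test_identical_groups_not_significant(self):
        table = differential_expression(
            make_expr({"g": [100, 100, 100, 100]}), "A", "B"
        )
        assert table.loc["g", "p_value"] == 1.0
        assert table.loc["g", "call"] == "ns"

    def test_fold_change_gate_is_strict(self):
        """A highly significant 1.4-fold change is below the >1.5-fold
        gate and must stay non-significant."""
        table = differential_expression(
            make_expr({"g": [140.0, 140.0001, 100.0, 100.0001]}), "A", "B"
        )
        assert table.loc["g", "p_value"] < 0.001
        assert table.loc["g", "fold_change"] == pytest.approx(1.4, rel=1e-4)
        assert table.loc["g", "call"] == "ns"

    def test_down_call_symmetric(self):
        table = differential_expression(
            make_expr({"g": [100, 101, 200, 202]}), "A", "B"
        )
        assert table.loc["g", "call"] == "down"

    def test_p_values_match_reference_t_distribution(self):
        """p equals the closed-form pooled-variance Student's t tail
        probability (on the log2 scale the test operates on)."""
        rows = {"g1": [210.0, 195.0, 98.0, 104.0], "g2": [120.0, 133.0, 118.0, 125.0]}
        table = differential_expression(make_expr(rows), "A", "B")
        for g, vals in rows.items():
            x = np.log2(vals[:2])
            y = np.log2(vals[2:])
            sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (0.5 + 0.5))
            p_ref = 2 * stats.t.sf(abs(t), df=2)
            assert table.loc[g, "p_value"] == pytest.approx(p_ref, abs=1e-10)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(OmicsValidationError):
            differential_expression(make_expr({"g": [0.0, 1, 1, 1]}), "A", "B")

    def test_single_replicate_rejected(self):
        values = pd.DataFrame({"g": [1.0, 2.0]}, index=["A_1", "B_1"]).T
        expr = ExpressionTable(values=values, groups={"A_1": "A", "B_1": "B"})
        with pytest.raises(OmicsValidationError):
            differential_expression(expr, "A", "B")


class TestRankGeneScores:
    def test_scores_follow_rank_formula(self):
        expr = {f"g{i:02d}": float(i) for i in range(1, 11)}   # g10 highest
        table = rank_gene_scores(expr, 0.3).table
        assert table.loc["g10", "rank"] == 10
        assert table.loc["g10", "score"] == pytest.approx(10 / 3.0)
        assert table.loc["g03", "score"] == pytest.approx(1.0)   # 30th pct pivot
        assert table.loc["g01", "score"] == pytest.approx(1 / 3.0)

    def test_ranks_are_permutation_with_lexicographic_ties(self):
        expr = {"b": 5.0, "a": 5.0, "c": 1.0}
        table = rank_gene_scores(expr).table
        assert sorted(table["rank"]) == [1, 2, 3]
        assert table.loc["c", "rank"] == 1
        # tie between a and b: lexicographically smaller id ranks first
        assert table.loc["a", "rank"] == 2
        assert table.loc["b", "rank"] == 3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=99))
    def test_scale_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        expr = pd.Series(rng.lognormal(size=12), index=[f"g{i}" for i in range(12)])
        base = rank_gene_scores(expr).table
        scaled = rank_gene_scores(expr * k).table
        assert (base["rank"] == scaled["rank"]).all()
        assert np.allclose(base["score"], scaled["score"])

    def test_empty_input_rejected(self):
        with pytest.raises(OmicsValidationError):
            rank_gene_scores({})


def make_metabolome(rows: dict[str, list[float | None]]) -> MetabolomeTable:
    cols = ["LCSC_1", "LCSC_2", "nonLCSC_1", "nonLCSC_2"]
    values = pd.DataFrame(rows, index=cols, dtype=float).T
    classes = pd.Series("standard", index=values.index)
    return MetabolomeTable(values=values, classes=classes)


NA = None


class TestDetection:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([30, 32, 10, 10], "both"),
            ([30, 32, NA, NA], "A_only"),
            ([NA, NA, 10, 11], "B_only"),
            ([NA, NA, NA, NA], "neither"),
            ([30, NA, NA, NA], "irreproducible"),
            ([30, 32, 10, NA], "irreproducible"),
        ],
    )
    def test_categories(self, row, expected):
        table = make_metabolome({"m": row})
        out = classify_detection(table, "LCSC", "nonLCSC")
        assert out.loc["m", "category"] == expected

    def test_categories_partition(self):
        rng = np.random.default_rng(7)
        rows = {}
        for i in range(40):
            row = [float(x) if rng.random() > 0.4 else NA
                   for x in rng.lognormal(size=4)]
            rows[f"m{i}"] = row
        out = classify_detection(make_metabolome(rows), "LCSC", "nonLCSC")
        assert len(out) == 40
        assert out["category"].isin(
            ["both", "A_only", "B_only", "neither", "irreproducible"]
        ).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(OmicsValidationError):
            classify_detection(make_metabolome({"m": [1, 1, 1, 1]}), "LCSC", "typo")


class TestFoldChanges:
    def test_planted_fold_change_flagged(self):
        out = metabolite_fold_changes(
            make_metabolome({"m": [30, 32, 10, 10]}), "LCSC", "nonLCSC"
        )
        assert out.loc["m", "fold_change"] == pytest.approx(3.1)
        assert out.loc["m", "flagged"]

    def test_unchanged_not_flagged(self):
        out = metabolite_fold_changes(
            make_metabolome({"m": [10, 10, 10, 10]}), "LCSC", "nonLCSC"
        )
        assert out.loc["m", "fold_change"] == pytest.approx(1.0)
        assert not out.loc["m", "flagged"]

    def test_exclusive_detection_excluded_not_divided(self):
        out = metabolite_fold_changes(
            make_metabolome({"m": [10, 10, NA, NA]}), "LCSC", "nonLCSC"
        )
        assert np.isnan(out.loc["m", "fold_change"])
        assert out.loc["m", "reason"] == "excluded: A_only"


class TestProductionTargets:
    @pytest.fixture
    def model(self):
        return build_model(
            "m", ["lac_c", "B"],
            [("R", {"lac_c": -1, "B": 1}, 0, 10), ("BIO", {"B": -1}, 0, 10)],
            "BIO",
        )

    def test_synonym_mapping(self, model):
        table = make_metabolome({"lactate": [1, 1, 1, 1]})
        matched, unmatched = production_targets(table, model, {"lactate": "lac_c"})
        assert matched == {"lac_c"}
        assert unmatched == []

    def test_unmatched_reported(self, model):
        table = make_metabolome({"mystery": [1, 1, 1, 1]})
        matched, unmatched = production_targets(table, model, {})
        assert matched == frozenset()
        assert unmatched == ["mystery"]

    def test_empty_metabolome(self, model):
        table = make_metabolome({})
        matched, unmatched = production_targets(table, model, {})
        assert matched == frozenset() and unmatched == []
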