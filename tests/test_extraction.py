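"""Weights, MILP extraction vs subset enumeration, tasks, gap-filling."""

import pytest

from contextgem.extraction import (
    ExtractionError,
    GapfillError,
    MetabolicTask,
    check_tasks,
    extract_context_model,
    gapfill_growth,
    reaction_weights,
    read_tasks,
    tasks_satisfied,
    write_tasks,
)
from contextgem.model import Medium, apply_medium

from conftest import build_model
from oracles import best_subsets_by_enumeration, min_gapfill_by_enumeration


class TestReactionWeights:
    @pytest.fixture
    def model(self):
        return build_model(
            "w", ["A", "B"],
            [
                ("R_OR", {"A": -1, "B": 1}, 0, 10, "G1 or G2"),
                ("R_AND", {"A": -1, "B": 1}, 0, 10, "G1 and G2"),
                ("R_NONE", {"A": -1, "B": 1}, 0, 10),
                ("BIO", {"B": -1}, 0, 10),
            ],
            "BIO",
        )

    def test_or_takes_max_and_takes_min(self, model):
        w = reaction_weights(model, {"G1": 2.0, "G2": 0.5})
        assert w["R_OR"] == pytest.approx(1.0)     # max(2.0, 0.5) - 1
        assert w["R_AND"] == pytest.approx(-0.5)   # min(2.0, 0.5) - 1

    def test_empty_gpr_weight_zero(self, model):
        w = reaction_weights(model, {"G1": 2.0, "G2": 0.5})
        assert w["R_NONE"] == 0.0
        assert w["BIO"] == 0.0

    def test_missing_gene_score_is_pivot_neutral(self, model):
        w = reaction_weights(model, {"G1": 2.0})
        assert w["R_AND"] == pytest.approx(0.0)    # min(2.0, default 1.0) - 1


def two_route_universal():
    """EX -> S; high-weight route P (2 steps) and negative route Q (2
    steps) both make B; RZ (negative) is the only producer of Z; RT
    (negative) the only producer of T."""
    return build_model(
        "uni",
        ["S", "X1", "Y1", "B", "Z", "T"],
        [
            ("EX_S", {"S": -1}, -10, 0),
            ("RP1", {"S": -1, "X1": 1}, 0, 1000),
            ("RP2", {"X1": -1, "B": 1}, 0, 1000),
            ("RQ1", {"S": -1, "Y1": 1}, 0, 1000),
            ("RQ2", {"Y1": -1, "B": 1}, 0, 1000),
            ("RZ", {"S": -1, "Z": 1}, 0, 1000),
            ("RT", {"S": -1, "T": 1}, 0, 1000),
            ("BIOMASS", {"B": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


WEIGHTS = {
    "EX_S": 0.1, "RP1": 1.0, "RP2": 1.0, "RQ1": -0.5, "RQ2": -0.5,
    "RZ": -0.5, "RT": -0.8, "BIOMASS": 0.2,
}


class TestExtraction:
    def test_keeps_positive_route_drops_negative(self):
        uni = two_route_universal()
        result = extract_context_model(uni, WEIGHTS, required_production={"B"})
        assert {"RP1", "RP2", "EX_S"} <= result.kept
        assert {"RQ1", "RQ2", "RZ", "RT"}.isdisjoint(result.kept)
        best_obj, best_sets = best_subsets_by_enumeration(
            uni, WEIGHTS, required={"B"}
        )
        assert result.objective_value == pytest.approx(best_obj, abs=1e-6)
        assert result.kept in best_sets

    def test_negative_weight_reaction_retained_for_required_metabolite(self):
        uni = two_route_universal()
        result = extract_context_model(uni, WEIGHTS, required_production={"B", "Z"})
        assert "RZ" in result.kept
        best_obj, best_sets = best_subsets_by_enumeration(
            uni, WEIGHTS, required={"B", "Z"}
        )
        assert result.objective_value == pytest.approx(best_obj, abs=1e-6)
        assert result.kept in best_sets

    def test_all_positive_weights_keep_everything(self):
        # make the network flux-consistent by draining the dead ends
        uni = two_route_universal()
        consistent = build_model(
            "uni_fc", list(uni.metabolites),
            [(r.id, r.stoich, r.lb, r.ub) for r in uni.reactions.values()]
            + [("EX_Z", {"Z": -1}, 0, 1000), ("EX_T", {"T": -1}, 0, 1000)],
            "BIOMASS",
        )
        positive = {rid: 0.5 for rid in consistent.reactions}
        result = extract_context_model(consistent, positive, required_production={"B"})
        assert result.kept == frozenset(consistent.reactions)

    def test_task_forces_negative_weight_reaction(self):
        uni = two_route_universal()
        task = MetabolicTask("need_T", inputs={"S": 10}, outputs={"T": 1})
        result = extract_context_model(
            uni, WEIGHTS, required_production={"B"}, tasks=[task]
        )
        assert "RT" in result.kept
        best_obj, best_sets = best_subsets_by_enumeration(
            uni, WEIGHTS, required={"B"}, tasks=[task]
        )
        assert result.objective_value == pytest.approx(best_obj, abs=1e-6)
        assert result.kept in best_sets

    def test_idempotent_reextraction(self):
        uni = two_route_universal()
        first = extract_context_model(uni, WEIGHTS, required_production={"B"})
        again = extract_context_model(
            first.model, {r: WEIGHTS[r] for r in first.model.reactions},
            required_production={"B"},
        )
        assert again.kept == first.kept

    def test_monotone_in_added_positive_reaction(self):
        """Adding a flux-consistent positive-weight reaction never lowers
        the extraction objective."""
        uni = two_route_universal()
        base = extract_context_model(uni, WEIGHTS, required_production={"B"})
        bigger = build_model(
            "uni+", list(uni.metabolites) + ["W"],
            [(r.id, r.stoich, r.lb, r.ub) for r in uni.reactions.values()]
            + [("RW", {"S": -1, "W": 1}, 0, 1000), ("EX_W", {"W": -1}, 0, 1000)],
            "BIOMASS",
        )
        grown = extract_context_model(
            bigger, {**WEIGHTS, "RW": 0.3, "EX_W": 0.3}, required_production={"B"}
        )
        assert grown.objective_value >= base.objective_value - 1e-9

    def test_unsatisfiable_requirement_diagnosed(self):
        uni = two_route_universal()
        blocked = uni.with_bounds({"RZ": (0, 0)})
        with pytest.raises(ExtractionError, match="required metabolite"):
            extract_context_model(blocked, WEIGHTS, required_production={"Z"})


class TestCheckTasks:
    def test_producible_output_passes(self, chain_model):
        task = MetabolicTask("make_B", inputs={"A": 10}, outputs={"B": 1})
        report = check_tasks(chain_model, [task])
        assert report["make_B"]["status"] == "pass"
        assert tasks_satisfied(report)

    def test_unproducible_output_fails(self, chain_model):
        task = MetabolicTask("impossible", inputs={}, outputs={"B": 1})
        report = check_tasks(chain_model, [task])
        assert report["impossible"]["status"] == "fail"
        assert report["impossible"]["violation"]

    def test_should_fail_passing_flagged_on_leaky_model(self):
        # stoichiometrically inconsistent internal cycle: W -> 2B, B -> W
        # creates B from nothing even with every boundary closed
        leaky = build_model(
            "leak", ["W", "B"],
            [("R1", {"W": -1, "B": 2}, 0, 10), ("R2", {"B": -1, "W": 1}, 0, 10),
             ("BIO", {"B": -1}, 0, 10)],
            "BIO",
        )
        task = MetabolicTask("no_free_lunch", outputs={"B": 0.5}, should_fail=True)
        report = check_tasks(leaky, [task])
        assert report["no_free_lunch"]["status"] == "pass"
        assert report["no_free_lunch"]["violation"]

    def test_unknown_metabolite_errors_only_that_task(self, chain_model):
        tasks = [
            MetabolicTask("bad", inputs={"NOPE": 1}, outputs={"B": 1}),
            MetabolicTask("good", inputs={"A": 10}, outputs={"B": 1}),
        ]
        report = check_tasks(chain_model, tasks)
        assert report["bad"]["status"] == "error"
        assert report["good"]["status"] == "pass"

    def test_json_round_trip(self, tmp_path):
        tasks = [
            MetabolicTask("t1", "desc", {"A": 10.0}, {"B": 1.0}, False),
            MetabolicTask("t2", "", {}, {"B": 0.1}, True),
        ]
        path = tmp_path / "tasks.json"
        write_tasks(tasks, path)
        assert read_tasks(path) == tasks


class TestGapfill:
    def universal(self):
        return build_model(
            "uni", ["A", "B", "C"],
            [
                ("EX_A", {"A": -1}, -10, 0),
                ("R_AB", {"A": -1, "B": 1}, 0, 1000),
                ("R_BC", {"B": -1, "C": 1}, 0, 1000),
                ("R_AC", {"A": -1, "C": 1}, 0, 1000),
                ("BIOMASS", {"C": -1}, 0, 1000),
            ],
            "BIOMASS",
        )

    def test_single_missing_reaction_restored(self):
        uni = self.universal()
        # model lacks both B-route steps and the direct A->C shortcut is
        # also absent: the single cheapest repair is R_AC
        model = uni.subset({"EX_A", "R_AB", "BIOMASS"})
        result = gapfill_growth(model, uni, min_growth=1.0)
        k_min, _ = min_gapfill_by_enumeration(model, uni, 1.0)
        assert len(result.added) == k_min == 1
        assert result.added == ["R_AC"] or result.added == ["R_BC"]
        assert result.growth >= 1.0

    def test_already_growing_returns_empty_set(self):
        uni = self.universal()
        model = uni.subset({"EX_A", "R_AC", "BIOMASS"})
        result = gapfill_growth(model, uni, min_growth=1.0)
        assert result.added == []

    def test_minimality_matches_enumeration_with_medium(self):
        uni = self.universal()
        medium = Medium(uptake={"EX_A": 10.0})
        model = uni.subset({"BIOMASS"})
        result = gapfill_growth(model, uni, medium, min_growth=1.0)
        k_min, _ = min_gapfill_by_enumeration(model, apply_medium(uni, medium), 1.0)
        assert len(result.added) == k_min
        assert result.growth >= 1.0

    def test_impossible_target_reports_dead_ends(self):
        uni = build_model(
            "deaduni", ["A", "C"],
            [
                ("EX_A", {"A": -1}, -10, 0),
                ("R_AX", {"A": -1}, 0, 0),
                ("BIOMASS", {"C": -1}, 0, 1000),   # C has no producer anywhere
            ],
            "BIOMASS",
        )
        model = uni.subset({"EX_A", "BIOMASS"})
        with pytest.raises(GapfillError, match="C"):
            gapfill_growth(model, uni, min_growth=1.0)
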