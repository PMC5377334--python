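"""Model container, JSON/SBML IO, medium application."""

import math

import pytest

from contextgem.model import (
    MetabolicModel,
    Medium,
    Metabolite,
    ModelValidationError,
    Reaction,
    apply_medium,
    genes_of_reactions,
    read_medium,
    read_model,
    write_medium,
    write_model,
)
from contextgem.gpr import parse_gpr

from conftest import build_model


def _models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    if a.biomass_reaction_id != b.biomass_reaction_id:
        return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if ra.stoich != rb.stoich or ra.lb != rb.lb or ra.ub != rb.ub:
            return False
        if ra.gpr.to_string() != rb.gpr.to_string():
            return False
    return True


@pytest.fixture
def gpr_model():
    return build_model(
        "toy3",
        ["A", "B", "C"],
        [
            ("EX_A", {"A": -1}, -10, 0),
            ("R1", {"A": -1, "B": 1}, 0, 1000, "(G1 and G2) or G3"),
            ("BIOMASS", {"B": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


def test_counts_and_validation(gpr_model):
    assert len(gpr_model.reactions) == 3
    assert len(gpr_model.metabolites) == 3
    assert gpr_model.genes == {"G1", "G2", "G3"}
    assert gpr_model.exchange_ids == ["EX_A"]


def test_undeclared_metabolite_names_reaction():
    with pytest.raises(ModelValidationError, match="RX"):
        build_model("bad", ["A"], [("RX", {"A": -1, "X": 1}, 0, 10)], "RX")


def test_bound_order_validated():
    with pytest.raises(ModelValidationError, match="lower bound"):
        build_model("bad", ["A"], [("R", {"A": 1}, 5, 1)], "R")


def test_missing_biomass_rejected():
    with pytest.raises(ModelValidationError, match="biomass"):
        build_model("bad", ["A"], [("R", {"A": 1}, 0, 1)], "NOPE")


@pytest.mark.parametrize("fmt", ["json", "sbml"])
def test_write_read_round_trip(gpr_model, tmp_path, fmt):
    path = tmp_path / f"model.{fmt}"
    write_model(gpr_model, path, fmt)
    back = read_model(path, fmt)
    assert _models_equal(gpr_model, back)


def test_json_round_trip_preserves_infinite_bounds(tmp_path):
    m = build_model("inf", ["A"], [("EX_A", {"A": -1}, -math.inf, math.inf),
                                   ("B", {"A": -1}, 0, 1)], "B")
    path = tmp_path / "m.json"
    write_model(m, path, "json")
    back = read_model(path, "json")
    assert back.reactions["EX_A"].lb == -math.inf
    assert back.reactions["EX_A"].ub == math.inf


def test_json_parse_error_reports_location(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"metabolites": [')
    with pytest.raises(Exception, match="line"):
        read_model(path, "json")


def test_empty_gpr_omitted_in_sbml(gpr_model, tmp_path):
    path = tmp_path / "m.xml"
    write_model(gpr_model, path, "sbml")
    back = read_model(path, "sbml")
    assert back.reactions["BIOMASS"].gpr.is_empty
    assert back.reactions["R1"].gpr.genes() == {"G1", "G2", "G3"}


def test_genes_of_reactions_union(gpr_model):
    assert genes_of_reactions(gpr_model, ["R1"]) == {"G1", "G2", "G3"}
    assert genes_of_reactions(gpr_model, ["BIOMASS"]) == frozenset()
    assert genes_of_reactions(gpr_model, []) == frozenset()
    with pytest.raises(KeyError):
        genes_of_reactions(gpr_model, ["NOPE"])


class TestApplyMedium:
    def test_uptake_bound_set_negative(self, gpr_model):
        out = apply_medium(gpr_model, Medium(uptake={"EX_A": 3.0}))
        assert out.reactions["EX_A"].lb == -3.0

    def test_absent_exchange_closed(self, loop_model):
        out = apply_medium(loop_model, Medium(uptake={}))
        assert out.reactions["EX_A"].lb == 0.0

    def test_secretion_and_internals_untouched(self, gpr_model):
        out = apply_medium(gpr_model, Medium(uptake={"EX_A": 3.0}))
        assert out.reactions["EX_A"].ub == gpr_model.reactions["EX_A"].ub
        assert out.reactions["R1"].lb == gpr_model.reactions["R1"].lb
        assert out.reactions["R1"].stoich == gpr_model.reactions["R1"].stoich

    def test_input_model_not_modified(self, gpr_model):
        before = gpr_model.reactions["EX_A"].lb
        apply_medium(gpr_model, Medium(uptake={"EX_A": 3.0}))
        assert gpr_model.reactions["EX_A"].lb == before

    def test_internal_reaction_in_medium_rejected(self, gpr_model):
        with pytest.raises(ModelValidationError, match="R1"):
            apply_medium(gpr_model, Medium(uptake={"R1": 5.0}))

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ModelValidationError):
            Medium(uptake={"EX_A": -1.0})


def test_medium_tsv_round_trip(tmp_path):
    medium = Medium(uptake={"EX_A": 10.0, "EX_B": 0.5})
    path = tmp_path / "medium.tsv"
    write_medium(medium, path)
    assert read_medium(path).uptake == medium.uptake


def test_subset_drops_unused_metabolites(loop_model):
    sub = loop_model.subset({"EX_A", "R_AB", "BIOMASS"})
    assert set(sub.reactions) == {"EX_A", "R_AB", "BIOMASS"}
    assert set(sub.metabolites) == {"A", "B"}
    assert sub.biomass_reaction_id == "BIOMASS"
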