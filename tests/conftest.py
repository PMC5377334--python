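import pytest

from contextgem.gpr import parse_gpr
from contextgem.model import MetabolicModel, Metabolite, Reaction


def build_model(mid, mets, rxns, biomass):
    """Terse model builder: mets = list of ids, rxns = list of
    (id, stoich, lb, ub[, gpr])."""
    metabolites = {m: Metabolite(m) for m in mets}
    reactions = {}
    for spec in rxns:
        rid, stoich, lb, ub = spec[:4]
        gpr = parse_gpr(spec[4]) if len(spec) > 4 else parse_gpr("")
        reactions[rid] = Reaction(rid, dict(stoich), lb=lb, ub=ub, gpr=gpr)
    return MetabolicModel(
        id=mid, metabolites=metabolites, reactions=reactions,
        biomass_reaction_id=biomass,
    )


@pytest.fixture
def chain_model():
    """-> A -> B -> biomass, uptake capped at 10."""
    return build_model(
        "chain",
        ["A", "B"],
        [
            ("EX_A", {"A": -1}, -10, 0),
            ("R_AB", {"A": -1, "B": 1}, 0, 1000),
            ("BIOMASS", {"B": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


@pytest.fixture
def two_branch_model():
    """Shared uptake 10 feeding two routes with biomass yields 1.0 / 0.5."""
    return build_model(
        "branch",
        ["S", "P"],
        [
            ("EX_S", {"S": -1}, -10, 0),
            ("R_HI", {"S": -1, "P": 1.0}, 0, 1000),
            ("R_LO", {"S": -1, "P": 0.5}, 0, 1000),
            ("BIOMASS", {"P": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


@pytest.fixture
def diamond_model():
    """-> A; A -> B via R2 or R3; B -> biomass."""
    return build_model(
        "diamond",
        ["A", "B"],
        [
            ("EX_A", {"A": -1}, -10, 0),
            ("R2", {"A": -1, "B": 1}, 0, 1000),
            ("R3", {"A": -1, "B": 1}, 0, 1000),
            ("BIOMASS", {"B": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


@pytest.fixture
def loop_model():
    """Growth chain plus a bounded two-reaction cycle independent of
    biomass (a growth-decoupled free loop)."""
    return build_model(
        "loop",
        ["A", "B", "X", "Y"],
        [
            ("EX_A", {"A": -1}, -10, 0),
            ("R_AB", {"A": -1, "B": 1}, 0, 1000),
            ("BIOMASS", {"B": -1}, 0, 1000),
            ("L1", {"X": -1, "Y": 1}, 0, 5),
            ("L2", {"Y": -1, "X": 1}, 0, 5),
        ],
        "BIOMASS",
    )


@pytest.fixture
def reversible_model():
    """A reversible interconversion feeding biomass; 6 reactions."""
    return build_model(
        "rev",
        ["A", "B", "C"],
        [
            ("EX_A", {"A": -1}, -10, 0),
            ("R_AB", {"A": -1, "B": 1}, -1000, 1000),
            ("R_BC", {"B": -1, "C": 1}, 0, 1000),
            ("EX_C", {"C": -1}, 0, 1000),
            ("BIOMASS", {"C": -1}, 0, 1000),
        ],
        "BIOMASS",
    )
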