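"""Constraint-based metabolic model container and file IO.

The model holds stoichiometry, flux bounds, GPR rules and a designated
biomass reaction.  Sign convention for boundary (exchange) reactions:
they are written as ``met ->`` (the metabolite leaving the system), so
positive flux is secretion and negative flux is uptake.  Reversibility
is encoded purely by a negative lower bound.

Two on-disk formats are supported: SBML Level 3 (the community
interchange format, delegated to COBRApy/libsbml) and a small JSON
dialect used for readable toy fixtures::

    {"metabolites": [{"id", "name", "compartment"}],
     "reactions":   [{"id", "stoich": {met: coef}, "lb", "ub",
                      "gpr", "subsystem"}],
     "biomass": "<reaction id>"}

In JSON, ``lb``/``ub`` of ``null`` mean unbounded (-inf/+inf).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .gpr import EMPTY_GPR, GprRule, parse_gpr


class ModelValidationError(ValueError):
    pass


class ModelFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: dict[str, float]          # metabolite id -> coefficient
    lb: float = 0.0
    ub: float = 1000.0
    gpr: GprRule = EMPTY_GPR
    subsystem: str = ""

    def is_boundary(self) -> bool:
        return len(self.stoich) == 1


@dataclass
class MetabolicModel:
    """A validated stoichiometric model.

    ``genes`` is derived from the GPR rules at construction; exchange
    reactions are the single-metabolite boundary reactions other than
    the biomass reaction.
    """

    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str
    genes: frozenset[str] = field(init=False)

    def __post_init__(self):
        self.validate()
        self.genes = frozenset(
            g for r in self.reactions.values() for g in r.gpr.genes()
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoich:
                if met not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )
            if rxn.lb > rxn.ub:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lower bound {rxn.lb} > upper bound {rxn.ub}"
                )
        if self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    # -- views -----------------------------------------------------------
    @property
    def exchange_ids(self) -> list[str]:
        return [
            r.id
            for r in self.reactions.values()
            if r.is_boundary() and r.id != self.biomass_reaction_id
        ]

    def subset(self, reaction_ids, id_suffix: str = "") -> "MetabolicModel":
        """New model restricted to ``reaction_ids`` (biomass kept only if
        listed); unreferenced metabolites are dropped."""
        keep = set(reaction_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise KeyError(f"unknown reaction ids: {sorted(missing)}")
        rxns = {rid: self.reactions[rid] for rid in self.reactions if rid in keep}
        used_mets = {m for r in rxns.values() for m in r.stoich}
        mets = {mid: self.metabolites[mid] for mid in self.metabolites if mid in used_mets}
        # a certifying subnetwork may drop the biomass reaction; keep a
        # deterministic placeholder so the subset is still a valid model
        biomass = (
            self.biomass_reaction_id
            if self.biomass_reaction_id in rxns
            else min(rxns)
        )
        return MetabolicModel(
            id=self.id + id_suffix,
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=biomass,
        )

    def with_bounds(self, new_bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy with some reaction bounds replaced."""
        rxns = dict(self.reactions)
        for rid, (lb, ub) in new_bounds.items():
            rxns[rid] = replace(rxns[rid], lb=lb, ub=ub)
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=rxns,
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def stoichiometric_frame(self) -> pd.DataFrame:
        """Dense S matrix as metabolites x reactions DataFrame."""
        df = pd.DataFrame(
            0.0, index=sorted(self.metabolites), columns=list(self.reactions)
        )
        for rid, rxn in self.reactions.items():
            for met, coef in rxn.stoich.items():
                df.loc[met, rid] = coef
        return df


# -- medium --------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """Maximum uptake magnitudes (mmol gDW^-1 h^-1) per exchange reaction."""

    uptake: dict[str, float]

    def __post_init__(self):
        for rid, mag in self.uptake.items():
            if mag < 0:
                raise ModelValidationError(
                    f"medium uptake for {rid!r} must be nonnegative, got {mag}"
                )


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Constrain uptake to the medium: every exchange reaction's lower
    bound becomes -(medium magnitude) if listed, else 0 (no uptake).
    Secretion bounds are untouched; the input model is not modified."""
    exchanges = set(model.exchange_ids)
    bad = set(medium.uptake) - exchanges
    if bad:
        raise ModelValidationError(
            f"medium names non-exchange reactions: {sorted(bad)}"
        )
    new_bounds = {}
    for rid in exchanges:
        rxn = model.reactions[rid]
        lb = -medium.uptake.get(rid, 0.0)
        new_bounds[rid] = (lb, rxn.ub)
    return model.with_bounds(new_bounds)


def read_medium(path) -> Medium:
    """Two-column TSV (exchange_reaction_id, max_uptake), header required."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ModelFormatError(f"medium file {path} needs two columns, got {df.shape[1]}")
    col_rid, col_mag = df.columns[:2]
    return Medium(uptake=dict(zip(df[col_rid].astype(str), df[col_mag].astype(float))))


def write_medium(medium: Medium, path) -> None:
    pd.DataFrame(
        {"exchange_reaction_id": list(medium.uptake), "max_uptake": list(medium.uptake.values())}
    ).to_csv(path, sep="\t", index=False)


# -- GPR convenience -----------------------------------------------------

def genes_of_reactions(model: MetabolicModel, reaction_ids) -> frozenset[str]:
    """Union of gene leaves over the GPR rules of the named reactions."""
    out: set[str] = set()
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction id {rid!r}")
        out |= model.reactions[rid].gpr.genes()
    return frozenset(out)


# -- JSON IO -------------------------------------------------------------

def _num_to_json(x: float):
    return None if math.isinf(x) else x


def _num_from_json(x, default: float) -> float:
    return default if x is None else float(x)


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": _num_to_json(r.lb),
                "ub": _num_to_json(r.ub),
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        "biomass": model.biomass_reaction_id,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = {
            m["id"]: Metabolite(
                id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "c")
            )
            for m in data["metabolites"]
        }
        rxns = {
            r["id"]: Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=_num_from_json(r.get("lb", 0.0), -math.inf),
                ub=_num_from_json(r.get("ub", 1000.0), math.inf),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
            )
            for r in data["reactions"]
        }
        biomass = data["biomass"]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed model JSON: {exc}") from exc
    return MetabolicModel(
        id=data.get("id", "model"), metabolites=mets, reactions=rxns,
        biomass_reaction_id=biomass,
    )


# -- SBML IO (via COBRApy/libsbml) --------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites.values()
    }
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions.values():
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[m]: c for m, c in r.stoich.items()})
        if not r.gpr.is_empty:
            cr.gene_reaction_rule = r.gpr.to_string()
    cm.objective = model.biomass_reaction_id
    return cm


def _from_cobra(cm, biomass_id: str | None = None) -> MetabolicModel:
    mets = {
        m.id: Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cm.metabolites
    }
    rxns = {}
    for cr in cm.reactions:
        rxns[cr.id] = Reaction(
            id=cr.id,
            stoich={m.id: float(c) for m, c in cr.metabolites.items()},
            lb=float(cr.lower_bound),
            ub=float(cr.upper_bound),
            gpr=parse_gpr(cr.gene_reaction_rule or ""),
            subsystem=cr.subsystem or "",
        )
    if biomass_id is None:
        from cobra.util.solver import linear_reaction_coefficients

        objective = linear_reaction_coefficients(cm)
        candidates = sorted(r.id for r, c in objective.items() if c != 0)
        biomass_id = candidates[0] if candidates else next(iter(rxns))
    return MetabolicModel(
        id=cm.id or "model", metabolites=mets, reactions=rxns,
        biomass_reaction_id=biomass_id,
    )


# -- public readers/writers ---------------------------------------------

def read_model(path, format: str = "json") -> MetabolicModel:
    """Read a model from ``path`` in ``format`` ('sbml' or 'json')."""
    if format == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(
                f"invalid JSON in {path}: line {exc.lineno} column {exc.colno}"
            ) from exc
        return model_from_dict(data)
    if format == "sbml":
        import cobra.io

        cm = cobra.io.read_sbml_model(str(path))
        return _from_cobra(cm)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "json") -> None:
    """Write a model losslessly so that :func:`read_model` recovers it."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
        return
    raise ValueError(f"unknown model format {format!r}")
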