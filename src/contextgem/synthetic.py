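"""Synthetic study generator with planted ground truth.

Emulates the inputs of a two-cell-type stem-cell metabolism study at toy
scale so that every pipeline stage can be exercised and verified without
external downloads:

* a universal toy metabolic model with one linear, growth-coupled biomass
  pathway and a set of growth-decoupled decoy conversions (bounded
  nutrient side-paths whose attainable flux is independent of growth);
* duplicate expression profiles for two groups with planted >=1.5-fold
  effects on known gene sets (multiplicative lognormal noise, the
  standard microarray intensity model);
* a metabolome table with planted fold changes and detection dropouts
  covering every detection category;
* a regulatory network whose master TF targets exactly (a fraction of)
  the growth-coupled pathway's genes while decoy TFs target only decoy
  genes.

Every output is a pure function of the :class:`SyntheticSpec` (seeded
NumPy generator), so identical specs give byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import MetabolicTask, write_tasks
from .gpr import parse_gpr
from .model import (
    MetabolicModel,
    Medium,
    Metabolite,
    Reaction,
    write_medium,
    write_model,
)
from .omics import ExpressionTable, MetabolomeTable
from .tf_rank import RegulatoryNetwork

GROUP_A = "LCSC"          # stem-like group carrying the planted effects
GROUP_B = "nonLCSC"

UPTAKE_LIMIT = 10.0       # main carbon source, mmol/gDW/h
DECOY_LIMIT = 5.0         # decoy nutrient caps, independent of biomass


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    n_coupled_pathway_length: int = 6     # reactions in the biomass chain
    n_decoy_reactions: int = 4
    n_genes: int = 240
    n_planted_up_genes: int = 20
    n_planted_down_genes: int = 10
    effect_size: float = 2.0              # fold effect on planted genes
    noise_sd: float = 0.1                 # lognormal sigma per replicate
    replicates: int = 2                   # per group ("duplicate profiles")
    n_tfs: int = 6
    master_tf_coverage: float = 1.0       # fraction of coupled genes targeted

    def __post_init__(self):
        if min(self.n_coupled_pathway_length, self.n_decoy_reactions,
               self.n_genes, self.n_planted_up_genes, self.n_tfs,
               self.replicates) <= 0:
            raise ValueError("all counts must be positive")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        n_special = (self.n_planted_up_genes + self.n_planted_down_genes
                     + self.n_decoy_reactions)
        if self.n_genes < n_special + 1:
            raise ValueError("n_genes too small for the planted sets")
        if self.n_planted_up_genes < self.n_coupled_pathway_length + 1:
            raise ValueError("planted up set must cover the coupled pathway genes")


@dataclass
class GroundTruth:
    coupled_reactions: list[str]      # chain + biomass: fluxes scale with growth
    decoy_reactions: list[str]
    coupled_genes: list[str]
    decoy_genes: list[str]
    planted_up: list[str]
    planted_down: list[str]
    master_tf: str


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    model: MetabolicModel
    medium: Medium
    tasks: list[MetabolicTask]
    expression: ExpressionTable
    metabolome: MetabolomeTable
    synonyms: dict[str, str]
    network: RegulatoryNetwork
    truth: GroundTruth


def _gene_pool(spec: SyntheticSpec) -> list[str]:
    width = len(str(spec.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]


def _partition_genes(spec: SyntheticSpec):
    pool = _gene_pool(spec)
    n_coupled = spec.n_coupled_pathway_length + 1   # one reaction is a complex
    coupled = pool[:n_coupled]
    planted_up = pool[: spec.n_planted_up_genes]
    planted_down = pool[
        spec.n_planted_up_genes: spec.n_planted_up_genes + spec.n_planted_down_genes
    ]
    n_used = spec.n_planted_up_genes + spec.n_planted_down_genes
    decoy = pool[n_used: n_used + spec.n_decoy_reactions]
    return pool, coupled, planted_up, planted_down, decoy


def generate_toy_model(spec: SyntheticSpec):
    """Build the universal toy model, its medium, a toy task list and the
    planted ground truth (coupled vs decoy reaction ids and gene sets)."""
    _, coupled_genes, planted_up, planted_down, decoy_genes = _partition_genes(spec)
    L = spec.n_coupled_pathway_length
    mets: dict[str, Metabolite] = {
        "S_e": Metabolite("S_e", "carbon source", "e"),
        "B_c": Metabolite("B_c", "biomass precursor", "c"),
    }
    for i in range(1, L):
        mets[f"M{i}_c"] = Metabolite(f"M{i}_c", f"pathway intermediate {i}", "c")
    rxns: dict[str, Reaction] = {
        "EX_S": Reaction("EX_S", {"S_e": -1.0}, lb=-UPTAKE_LIMIT, ub=1000.0,
                         subsystem="exchange"),
    }
    chain_mets = ["S_e"] + [f"M{i}_c" for i in range(1, L)] + ["B_c"]
    coupled_rxn_ids = []
    for k in range(L):
        rid = f"R{k + 1}"
        gpr = (
            f"{coupled_genes[0]} and {coupled_genes[L]}"
            if k == 0
            else coupled_genes[k]
        )
        rxns[rid] = Reaction(
            rid,
            {chain_mets[k]: -1.0, chain_mets[k + 1]: 1.0},
            lb=0.0, ub=1000.0,
            gpr=parse_gpr(gpr),
            subsystem="biomass pathway",
        )
        coupled_rxn_ids.append(rid)
    rxns["BIOMASS"] = Reaction("BIOMASS", {"B_c": -1.0}, lb=0.0, ub=1000.0,
                               subsystem="biomass")
    coupled_rxn_ids.append("BIOMASS")

    decoy_rxn_ids = []
    medium_uptake = {"EX_S": UPTAKE_LIMIT}
    tasks: list[MetabolicTask] = [
        MetabolicTask("t_biomass_precursor", "produce B from the carbon source",
                      inputs={"S_e": UPTAKE_LIMIT}, outputs={"B_c": 1.0}),
        MetabolicTask("t_first_intermediate", "produce M1 from the carbon source",
                      inputs={"S_e": UPTAKE_LIMIT}, outputs={"M1_c": 1.0}),
        MetabolicTask("t_chain_tail", "produce B from the first intermediate",
                      inputs={"M1_c": UPTAKE_LIMIT}, outputs={"B_c": 1.0}),
    ]
    for i in range(1, spec.n_decoy_reactions + 1):
        nut, prod = f"D{i}_e", f"P{i}_e"
        mets[nut] = Metabolite(nut, f"decoy nutrient {i}", "e")
        mets[prod] = Metabolite(prod, f"decoy product {i}", "e")
        rxns[f"EX_D{i}"] = Reaction(f"EX_D{i}", {nut: -1.0}, lb=-DECOY_LIMIT,
                                    ub=1000.0, subsystem="exchange")
        rid = f"DEC{i}"
        rxns[rid] = Reaction(
            rid, {nut: -1.0, prod: 1.0}, lb=0.0, ub=DECOY_LIMIT,
            gpr=parse_gpr(decoy_genes[i - 1]), subsystem="decoy",
        )
        decoy_rxn_ids.append(rid)
        rxns[f"EX_P{i}"] = Reaction(f"EX_P{i}", {prod: -1.0}, lb=0.0, ub=1000.0,
                                    subsystem="exchange")
        medium_uptake[f"EX_D{i}"] = DECOY_LIMIT
        tasks.append(
            MetabolicTask(f"t_decoy_{i}", f"convert decoy nutrient {i}",
                          inputs={nut: DECOY_LIMIT}, outputs={prod: 1.0})
        )
    tasks.append(
        MetabolicTask("t_no_free_lunch", "biomass precursor from nothing must fail",
                      inputs={}, outputs={"B_c": 0.1}, should_fail=True)
    )

    model = MetabolicModel(
        id=f"toy_universal_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )
    truth = GroundTruth(
        coupled_reactions=coupled_rxn_ids,
        decoy_reactions=decoy_rxn_ids,
        coupled_genes=list(coupled_genes),
        decoy_genes=list(decoy_genes),
        planted_up=list(planted_up),
        planted_down=list(planted_down),
        master_tf="",
    )
    return model, Medium(uptake=medium_uptake), tasks, truth


def generate_expression(
    spec: SyntheticSpec,
    gene_pool: list[str],
    planted_up: list[str],
    planted_down: list[str],
    rng: np.random.Generator,
) -> ExpressionTable:
    """Duplicate lognormal intensity profiles with planted fold effects in
    group A (multiplied by effect_size for up genes, divided for down)."""
    up, down = set(planted_up), set(planted_down)
    baseline = 100.0 * np.exp(0.5 * rng.standard_normal(len(gene_pool)))
    effect = np.array(
        [
            spec.effect_size if g in up else (1.0 / spec.effect_size if g in down else 1.0)
            for g in gene_pool
        ]
    )
    cols = {}
    for rep in range(1, spec.replicates + 1):
        noise = np.exp(spec.noise_sd * rng.standard_normal(len(gene_pool)))
        cols[f"{GROUP_A}_{rep}"] = baseline * effect * noise
    for rep in range(1, spec.replicates + 1):
        noise = np.exp(spec.noise_sd * rng.standard_normal(len(gene_pool)))
        cols[f"{GROUP_B}_{rep}"] = baseline * noise
    values = pd.DataFrame(cols, index=gene_pool)
    values.index.name = "gene"
    groups = {c: c.rsplit("_", 1)[0] for c in values.columns}
    return ExpressionTable(values=values, groups=groups)


DEFAULT_DROPOUTS = {
    "aspartate": "A_only",
    "glycerol": "B_only",
    "cystine": "neither",
    "ornithine": "neither",
    "taurine": "irreproducible",
}


def generate_metabolome(
    spec: SyntheticSpec,
    model: MetabolicModel,
    rng: np.random.Generator,
    fold_changes: dict[str, float] | None = None,
    dropouts: dict[str, str] | None = None,
):
    """Metabolome table + name->model-id synonym map.

    Chain metabolites appear as "standard" entries detected in both cell
    types (mapped to model ids through the synonym table); extra named
    metabolites realize the requested dropout categories and putative
    (relative-abundance) entries carry planted fold changes.
    """
    dropouts = DEFAULT_DROPOUTS if dropouts is None else dropouts
    model_mets = [m for m in model.metabolites if not m.startswith(("D", "P"))]
    synonyms = {f"met_{mid}": mid for mid in model_mets}
    if fold_changes is None:
        # plant increases on the biomass precursor and first intermediate,
        # mirroring elevated central-carbon pools in the stem-like state
        fold_changes = {"met_B_c": 2.0, "met_M1_c": 3.0}
    names = list(synonyms) + list(dropouts) + ["phosphocreatine_rel", "carnitine_rel"]
    classes, rows = {}, {}
    cols = [f"{GROUP_A}_{r}" for r in range(1, spec.replicates + 1)] + [
        f"{GROUP_B}_{r}" for r in range(1, spec.replicates + 1)
    ]
    for name in names:
        putative = name.endswith("_rel")
        classes[name] = "putative" if putative else "standard"
        base = float(np.exp(np.log(50.0) + 0.6 * rng.standard_normal()))
        fc = fold_changes.get(name, 2.0 if putative else 1.0)
        vals = {}
        for c in cols:
            group_a = c.startswith(GROUP_A)
            level = base * (fc if group_a else 1.0)
            vals[c] = level * float(np.exp(0.05 * rng.standard_normal()))
        cat = dropouts.get(name)
        if cat == "A_only":
            for c in vals:
                if c.startswith(GROUP_B):
                    vals[c] = np.nan
        elif cat == "B_only":
            for c in vals:
                if c.startswith(GROUP_A):
                    vals[c] = np.nan
        elif cat == "neither":
            vals = {c: np.nan for c in vals}
        elif cat == "irreproducible":
            vals[cols[0]] = np.nan       # one missing replicate in group A
        rows[name] = vals
    values = pd.DataFrame.from_dict(rows, orient="index")[cols]
    values.index.name = "metabolite"
    table = MetabolomeTable(values=values, classes=pd.Series(classes, name="class"))
    return table, synonyms


def generate_regulatory_network(
    spec: SyntheticSpec,
    coupled_genes: list[str],
    decoy_genes: list[str],
    rng: np.random.Generator,
) -> tuple[RegulatoryNetwork, str]:
    """One master TF covering the coupled genes; decoy TFs target only
    decoy genes.  All edges High confidence with experimental evidence."""
    if set(coupled_genes) & set(decoy_genes):
        raise ValueError("coupled and decoy gene sets must be disjoint")
    master = "TF01"
    n_master = max(1, int(round(spec.master_tf_coverage * len(coupled_genes))))
    edges = [(master, g) for g in coupled_genes[:n_master]]
    for k in range(2, spec.n_tfs + 1):
        tf = f"TF{k:02d}"
        n_targets = int(rng.integers(1, len(decoy_genes) + 1))
        chosen = rng.choice(decoy_genes, size=n_targets, replace=False)
        edges.extend((tf, g) for g in sorted(chosen))
    df = pd.DataFrame(edges, columns=["TF", "target"])
    df["confidence"] = "High"
    df["evidence"] = "Experimental"
    return RegulatoryNetwork.from_edges(df), master


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """The full coherent study: model, medium, tasks, expression,
    metabolome, regulatory network and ground truth."""
    rng = np.random.default_rng(spec.seed)
    model, medium, tasks, truth = generate_toy_model(spec)
    pool, coupled_genes, planted_up, planted_down, decoy_genes = _partition_genes(spec)
    expression = generate_expression(spec, pool, planted_up, planted_down, rng)
    metabolome, synonyms = generate_metabolome(spec, model, rng)
    network, master = generate_regulatory_network(
        spec, coupled_genes, decoy_genes, rng
    )
    truth.master_tf = master
    return SyntheticBundle(
        spec=spec,
        model=model,
        medium=medium,
        tasks=tasks,
        expression=expression,
        metabolome=metabolome,
        synonyms=synonyms,
        network=network,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Serialize the bundle (SBML + JSON model, TSVs, task JSON, ground
    truth JSON) into ``outdir``; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model_json": outdir / "model.json",
        "model_sbml": outdir / "model.xml",
        "medium": outdir / "medium.tsv",
        "tasks": outdir / "tasks.json",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "metabolome": outdir / "metabolome.tsv",
        "synonyms": outdir / "synonyms.tsv",
        "network": outdir / "network.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_model(bundle.model, paths["model_json"], "json")
    write_model(bundle.model, paths["model_sbml"], "sbml")
    write_medium(bundle.medium, paths["medium"])
    write_tasks(bundle.tasks, paths["tasks"])
    bundle.expression.values.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        {"sample": list(bundle.expression.groups),
         "group": list(bundle.expression.groups.values())}
    ).to_csv(paths["groups"], sep="\t", index=False)
    met = bundle.metabolome.values.copy()
    met.insert(0, "class", bundle.metabolome.classes)
    met.to_csv(paths["metabolome"], sep="\t")
    pd.DataFrame(
        {"name": list(bundle.synonyms), "model_id": list(bundle.synonyms.values())}
    ).to_csv(paths["synonyms"], sep="\t", index=False)
    bundle.network.edges.to_csv(paths["network"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({**asdict(bundle.truth), "spec": asdict(bundle.spec)}, fh, indent=1)
        fh.write("\n")
    return paths
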