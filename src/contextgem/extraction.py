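"""Context-specific model extraction, metabolic tasks and gap-filling.

Extraction selects a subnetwork of a universal model that is maximally
consistent with expression-derived reaction weights while remaining
functional: required metabolites must be producible (net production slack
>= epsilon), every included reaction must be able to carry flux in a
certifying steady-state flux vector, and a list of metabolic tasks must
pass (or fail, for negative controls) on the extracted network.  This is
an INIT-style mixed-integer program with a single certifying flux vector;
task constraints are enforced by iterative cut generation rather than one
monolithic MILP.

Gap-filling restores growth by adding a minimum-cardinality set of
reactions from the universal model, in the spirit of GrowMatch.

All MILPs are solved with HiGHS via scipy.optimize.milp, which is
deterministic for a fixed model ordering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .gpr import GprRule
from .lp import ZERO_FLUX_TOL, solve_fba
from .model import MetabolicModel, Medium, Reaction, apply_medium

BIG_M = 1000.0
EPSILON = 1e-4
DEFAULT_MIN_GROWTH = 1e-3


class ExtractionError(RuntimeError):
    pass


class GapfillError(RuntimeError):
    pass


# -- metabolic tasks -----------------------------------------------------

@dataclass(frozen=True)
class MetabolicTask:
    """A testable capability: with only ``inputs`` available (metabolite ->
    max uptake), each ``outputs`` metabolite must be producible at >= its
    stated minimum.  ``should_fail`` marks negative controls (the task
    must NOT pass, e.g. production from nothing on a mass-balanced
    network)."""

    id: str
    description: str = ""
    inputs: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, float] = field(default_factory=dict)
    should_fail: bool = False

    def __post_init__(self):
        for met, v in {**self.inputs, **self.outputs}.items():
            if v < 0:
                raise ValueError(f"task {self.id}: bound for {met} must be nonnegative")


def read_tasks(path) -> list[MetabolicTask]:
    """JSON array of {id, description, inputs:{met:max}, outputs:{met:min},
    should_fail}."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        MetabolicTask(
            id=t["id"],
            description=t.get("description", ""),
            inputs={k: float(v) for k, v in t.get("inputs", {}).items()},
            outputs={k: float(v) for k, v in t.get("outputs", {}).items()},
            should_fail=bool(t.get("should_fail", False)),
        )
        for t in data
    ]


def write_tasks(tasks: list[MetabolicTask], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "id": t.id,
                    "description": t.description,
                    "inputs": t.inputs,
                    "outputs": t.outputs,
                    "should_fail": t.should_fail,
                }
                for t in tasks
            ],
            fh,
            indent=1,
        )
        fh.write("\n")


def _task_model(model: MetabolicModel, task: MetabolicTask) -> MetabolicModel:
    """Close every boundary reaction (exchanges and biomass drain alike),
    then add temporary uptake sources for the task's inputs and demand
    sinks (lb = required minimum) for its outputs."""
    unknown = [m for m in {**task.inputs, **task.outputs} if m not in model.metabolites]
    if unknown:
        raise KeyError(f"task {task.id}: unknown metabolites {sorted(unknown)}")
    rxns = {}
    for rid, rxn in model.reactions.items():
        if rxn.is_boundary():
            rxns[rid] = Reaction(id=rid, stoich=rxn.stoich, lb=0.0, ub=0.0,
                                 gpr=rxn.gpr, subsystem=rxn.subsystem)
        else:
            rxns[rid] = rxn
    for met, cap in task.inputs.items():
        rid = f"__task_in_{met}"
        rxns[rid] = Reaction(id=rid, stoich={met: 1.0}, lb=0.0, ub=cap)
    for met, minimum in task.outputs.items():
        rid = f"__task_out_{met}"
        rxns[rid] = Reaction(id=rid, stoich={met: -1.0}, lb=minimum, ub=BIG_M)
    return MetabolicModel(
        id=model.id + "__task",
        metabolites=dict(model.metabolites),
        reactions=rxns,
        biomass_reaction_id=model.biomass_reaction_id,
    )


def _task_passes(model: MetabolicModel, task: MetabolicTask) -> tuple[bool, dict[str, float] | None]:
    tm = _task_model(model, task)
    first_out = next(iter(task.outputs), None)
    objective = f"__task_out_{first_out}" if first_out else tm.biomass_reaction_id
    res = solve_fba(tm, objective, "max")
    return res.ok, (res.fluxes if res.ok else None)


def _task_support(model: MetabolicModel, task: MetabolicTask) -> frozenset[str]:
    """Reactions of ``model`` that can carry flux in the task environment
    (boundaries closed, task inputs/demands installed).  A subnetwork can
    only pass the task using reactions from this set."""
    from .lp import run_fva

    from .lp import SolverError

    tm = _task_model(model, task)
    try:
        fva = run_fva(tm, fraction_of_optimum=None, reactions=list(model.reactions))
    except SolverError:      # task unsatisfiable even on the full network
        return frozenset()
    return frozenset(
        rid for rid, (lo, hi) in fva.ranges.items()
        if abs(lo) > ZERO_FLUX_TOL or abs(hi) > ZERO_FLUX_TOL
    )


def check_tasks(model: MetabolicModel, tasks: list[MetabolicTask]) -> dict[str, dict]:
    """Evaluate each task on the model.

    Returns per task a dict with ``status`` ("pass"/"fail"/"error"),
    ``violation`` (True when a should_fail task passes or a normal task
    fails) and a message.  One erroring task does not stop the others.
    """
    report: dict[str, dict] = {}
    for task in tasks:
        try:
            passed, _ = _task_passes(model, task)
        except KeyError as exc:
            report[task.id] = {"status": "error", "violation": True, "message": str(exc)}
            continue
        violation = passed if task.should_fail else not passed
        msg = ""
        if violation:
            msg = (
                "should_fail task passes (leaky network)"
                if task.should_fail
                else "required outputs not producible from allowed inputs"
            )
        report[task.id] = {
            "status": "pass" if passed else "fail",
            "violation": violation,
            "message": msg,
        }
    return report


def tasks_satisfied(report: dict[str, dict]) -> bool:
    return not any(r["violation"] for r in report.values())


# -- reaction weights ----------------------------------------------------

def reaction_weights(model: MetabolicModel, scores) -> dict[str, float]:
    """Expression weight per reaction from gene scores through the GPR:
    max over OR branches (isozymes), min over AND branches (complexes),
    then centered by -1 so genes below the 30th expression percentile
    (score < 1) discourage inclusion.  Empty GPR -> weight 0; genes
    without a score default to the pivot score 1.0 (weight-neutral)."""
    score_of = scores.score_of if hasattr(scores, "score_of") else (
        lambda g, default=1.0: scores.get(g, default)
    )
    weights = {}
    for rid, rxn in model.reactions.items():
        agg = rxn.gpr.aggregate(lambda g: score_of(g, 1.0))
        weights[rid] = 0.0 if agg is None else agg - 1.0
    return weights


# -- extraction ----------------------------------------------------------

@dataclass
class ExtractionResult:
    model: MetabolicModel
    objective_value: float
    weights: dict[str, float]
    status: str
    kept: frozenset[str]
    dropped: frozenset[str]
    task_report: dict[str, dict] = field(default_factory=dict)
    iterations: int = 1


def _solve_inclusion_milp(
    universal: MetabolicModel,
    weights: dict[str, float],
    required_production: frozenset[str] | set[str],
    cuts: list[tuple[str, frozenset[str]]],
    epsilon: float,
    big_m: float,
    soft_drains: frozenset[str] = frozenset(),
):
    """One INIT-style MILP: maximize sum(w_r * y_r) over binary inclusion
    y with a certifying flux vector.  ``cuts`` are ("include", S) rows
    requiring sum_{r in S} y_r >= 1, or ("exclude", S) rows requiring at
    least one member of S to be dropped.  ``soft_drains`` get a
    nonnegative production slack (no minimum), so reactions retained only
    for task capability can still carry certificate flux."""
    rids = list(universal.reactions)
    col = {rid: j for j, rid in enumerate(rids)}
    n = len(rids)
    mids = sorted(universal.metabolites)
    mrow = {mid: i for i, mid in enumerate(mids)}
    req = sorted(required_production)
    soft = sorted(set(soft_drains) - set(req))
    drains = req + soft
    # variables: vf (n) | vb (n) | y (n) | slack (len(drains))
    nvar = 3 * n + len(drains)
    lb = np.zeros(nvar)
    ub = np.zeros(nvar)
    for rid in rids:
        j = col[rid]
        r = universal.reactions[rid]
        ub[j] = min(max(r.ub, 0.0), big_m)
        ub[n + j] = min(max(-r.lb, 0.0), big_m)
        ub[2 * n + j] = 1.0
    for k, mid in enumerate(drains):
        lb[3 * n + k] = epsilon if mid in required_production else 0.0
        ub[3 * n + k] = big_m

    rows, cols, vals = [], [], []
    r_lo, r_hi = [], []
    nrow = 0

    def add_row(entries, lo, hi):
        nonlocal nrow
        for j, v in entries:
            rows.append(nrow)
            cols.append(j)
            vals.append(v)
        r_lo.append(lo)
        r_hi.append(hi)
        nrow += 1

    # steady state: S (vf - vb) - slack_req = 0
    entries_by_met: dict[int, list] = {i: [] for i in range(len(mids))}
    for rid in rids:
        j = col[rid]
        for met, coef in universal.reactions[rid].stoich.items():
            i = mrow[met]
            entries_by_met[i].append((j, coef))
            entries_by_met[i].append((n + j, -coef))
    for k, mid in enumerate(drains):
        entries_by_met[mrow[mid]].append((3 * n + k, -1.0))
    for i in range(len(mids)):
        add_row(entries_by_met[i], 0.0, 0.0)
    # coupling: vf + vb <= M y ; vf + vb >= eps y
    for rid in rids:
        j = col[rid]
        add_row([(j, 1.0), (n + j, 1.0), (2 * n + j, -big_m)], -np.inf, 0.0)
        add_row([(j, 1.0), (n + j, 1.0), (2 * n + j, -epsilon)], 0.0, np.inf)
    # cuts
    for kind, members in cuts:
        entries = [(2 * n + col[rid], 1.0) for rid in sorted(members)]
        if kind == "include":
            add_row(entries, 1.0, np.inf)
        else:  # exclude at least one
            add_row(entries, -np.inf, float(len(members) - 1))

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, nvar))
    c = np.zeros(nvar)
    for rid in rids:
        c[2 * n + col[rid]] = -weights[rid]
    integrality = np.zeros(nvar)
    integrality[2 * n: 3 * n] = 1
    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(r_lo), np.array(r_hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if res.status != 0:
        return None, res
    y = res.x[2 * n: 3 * n]
    kept = frozenset(rid for rid in rids if y[col[rid]] > 0.5)
    return kept, res


def extract_context_model(
    universal: MetabolicModel,
    weights: dict[str, float],
    required_production=frozenset(),
    tasks: list[MetabolicTask] | None = None,
    medium: Medium | None = None,
    epsilon: float = EPSILON,
    big_m: float = BIG_M,
    max_iterations: int = 50,
) -> ExtractionResult:
    """Select the maximum-weight functional subnetwork of ``universal``.

    Required metabolites get a net-production slack >= epsilon in the
    certifying flux vector; tasks are enforced by solving, testing the
    extracted network, adding cover cuts for violations and repeating
    (task passing is monotone in the reaction set, so the cuts are valid
    and the loop terminates at the true optimum).
    """
    missing = set(universal.reactions) - set(weights)
    if missing:
        raise ExtractionError(f"weights missing for reactions: {sorted(missing)}")
    unknown_req = set(required_production) - set(universal.metabolites)
    if unknown_req:
        raise ExtractionError(f"required metabolites not in model: {sorted(unknown_req)}")
    work = apply_medium(universal, medium) if medium is not None else universal
    tasks = tasks or []
    soft_drains = frozenset(
        m for t in tasks for m in t.outputs if m in work.metabolites
    )
    # support of a positive task on the full universal network: any
    # subnetwork passing the task must draw on these reactions, which
    # makes the cover cuts below sharp; computed lazily per failing task
    support: dict[str, frozenset[str]] = {}

    def task_support(task: MetabolicTask) -> frozenset[str]:
        if task.id not in support:
            support[task.id] = _task_support(work, task)
        return support[task.id]

    cuts: list[tuple[str, frozenset[str]]] = []
    for iteration in range(1, max_iterations + 1):
        kept, res = _solve_inclusion_milp(
            work, weights, frozenset(required_production), cuts, epsilon, big_m,
            soft_drains=soft_drains,
        )
        if kept is None:
            raise ExtractionError(_diagnose_infeasibility(
                work, weights, required_production, epsilon, big_m, soft_drains
            ))
        extracted = work.subset(kept)
        report = check_tasks(extracted, tasks) if tasks else {}
        new_cuts = []
        for task in tasks:
            rep = report.get(task.id)
            if rep is None or not rep["violation"]:
                continue
            if task.should_fail:
                # the leaky route must lose at least one reaction
                _, fluxes = _task_passes(extracted, task)
                active = frozenset(
                    rid for rid, v in (fluxes or {}).items()
                    if rid in kept and abs(v) > ZERO_FLUX_TOL
                )
                if not active:
                    raise ExtractionError(
                        f"should_fail task {task.id} passes with no active reactions"
                    )
                new_cuts.append(("exclude", active))
            else:
                outside = frozenset(task_support(task) - kept)
                if not outside:
                    raise ExtractionError(
                        f"task {task.id} fails even with its full reaction "
                        "support included"
                    )
                new_cuts.append(("include", outside))
        if not new_cuts:
            objective = sum(weights[rid] for rid in kept)
            return ExtractionResult(
                model=extracted,
                objective_value=objective,
                weights=dict(weights),
                status="optimal",
                kept=kept,
                dropped=frozenset(set(work.reactions) - kept),
                task_report=report,
                iterations=iteration,
            )
        cuts.extend(new_cuts)
    raise ExtractionError(
        f"task cut generation did not converge in {max_iterations} iterations "
        "(partial result discarded)"
    )


def _diagnose_infeasibility(work, weights, required_production, epsilon, big_m,
                            soft_drains=frozenset()) -> str:
    if required_production:
        kept, _ = _solve_inclusion_milp(work, weights, frozenset(), [], epsilon,
                                        big_m, soft_drains=soft_drains)
        if kept is not None:
            return (
                "extraction MILP infeasible: required metabolite production "
                f"cannot be satisfied for {sorted(required_production)}"
            )
    return "extraction MILP infeasible: network admits no certifying flux vector"


# -- gap filling ---------------------------------------------------------

@dataclass
class GapfillResult:
    added: list[str]
    growth: float
    status: str


def gapfill_growth(
    model: MetabolicModel,
    universal: MetabolicModel,
    medium: Medium | None = None,
    min_growth: float = DEFAULT_MIN_GROWTH,
    big_m: float = BIG_M,
) -> GapfillResult:
    """Add a minimum number of universal-model reactions so that the model
    reaches biomass flux >= ``min_growth`` on the medium.

    Candidate reactions are those of ``universal`` absent from ``model``.
    Returns the (cardinality-minimal) added set; if even the combined
    network cannot grow, raises with the limiting dead-end biomass
    precursors named.
    """
    not_in_universal = set(model.reactions) - set(universal.reactions)
    if not_in_universal:
        raise GapfillError(
            f"model reactions missing from universal: {sorted(not_in_universal)}"
        )
    combined = apply_medium(universal, medium) if medium is not None else universal
    base_ids = set(model.reactions)
    candidates = [rid for rid in combined.reactions if rid not in base_ids]

    # quick exits: model alone grows; combined network cannot grow
    model_on_medium = combined.subset(base_ids)
    own = solve_fba(model_on_medium)
    if own.ok and own.objective_value >= min_growth - 1e-9:
        return GapfillResult(added=[], growth=own.objective_value, status="optimal")
    full = solve_fba(combined)
    if not full.ok or full.objective_value < min_growth - 1e-9:
        dead = _dead_end_precursors(combined)
        raise GapfillError(
            "no reaction subset reaches the growth target; dead-end biomass "
            f"precursors: {dead if dead else '(none; medium/bounds limit growth)'}"
        )

    rids = list(combined.reactions)
    col = {rid: j for j, rid in enumerate(rids)}
    n = len(rids)
    mids = sorted(combined.metabolites)
    mrow = {mid: i for i, mid in enumerate(mids)}
    cand_set = set(candidates)
    # variables: v (n) | z (len(candidates))
    zcol = {rid: n + k for k, rid in enumerate(candidates)}
    nvar = n + len(candidates)
    lb = np.zeros(nvar)
    ub = np.zeros(nvar)
    for rid in rids:
        r = combined.reactions[rid]
        j = col[rid]
        lb[j] = max(r.lb, -big_m)
        ub[j] = min(r.ub, big_m)
    ub[n:] = 1.0
    lb[col[combined.biomass_reaction_id]] = max(
        lb[col[combined.biomass_reaction_id]], min_growth
    )

    rows, cols, vals, r_lo, r_hi = [], [], [], [], []
    nrow = 0

    def add_row(entries, lo, hi):
        nonlocal nrow
        for j, v in entries:
            rows.append(nrow)
            cols.append(j)
            vals.append(v)
        r_lo.append(lo)
        r_hi.append(hi)
        nrow += 1

    by_met: dict[int, list] = {i: [] for i in range(len(mids))}
    for rid in rids:
        for met, coef in combined.reactions[rid].stoich.items():
            by_met[mrow[met]].append((col[rid], coef))
    for i in range(len(mids)):
        add_row(by_met[i], 0.0, 0.0)
    for rid in candidates:
        j, zj = col[rid], zcol[rid]
        if ub[j] > 0:
            add_row([(j, 1.0), (zj, -ub[j])], -np.inf, 0.0)
        if lb[j] < 0:
            add_row([(j, 1.0), (zj, -lb[j])], 0.0, np.inf)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, nvar))
    c = np.zeros(nvar)
    c[n:] = 1.0
    integrality = np.zeros(nvar)
    integrality[n:] = 1
    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(r_lo), np.array(r_hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if res.status != 0:
        raise GapfillError(f"gap-fill MILP failed with status {res.status}")
    added = sorted(
        rid for rid in candidates if res.x[zcol[rid]] > 0.5
    )
    grown = combined.subset(base_ids | set(added))
    check = solve_fba(grown)
    growth = check.objective_value if check.ok else 0.0
    return GapfillResult(added=added, growth=growth, status="optimal")


def _dead_end_precursors(combined: MetabolicModel) -> list[str]:
    """Biomass substrates that cannot be net-produced in the combined
    network (checked with a temporary demand per precursor)."""
    biomass = combined.reactions[combined.biomass_reaction_id]
    precursors = [m for m, coef in biomass.stoich.items() if coef < 0]
    dead = []
    for met in precursors:
        rid = f"__probe_{met}"
        probe = MetabolicModel(
            id="probe",
            metabolites=dict(combined.metabolites),
            reactions={
                **{k: v for k, v in combined.reactions.items()
                   if k != combined.biomass_reaction_id},
                rid: Reaction(id=rid, stoich={met: -1.0}, lb=0.0, ub=BIG_M),
            },
            biomass_reaction_id=rid,
        )
        res = solve_fba(probe, rid, "max")
        if not res.ok or res.objective_value <= ZERO_FLUX_TOL:
            dead.append(met)
    return dead
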