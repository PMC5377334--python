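"""Flux balance analysis (FBA) and flux variability analysis (FVA).

Both operate on the steady-state flux polytope {v : S v = 0, lb <= v <= ub}.
FBA maximizes (or minimizes) a single reaction's flux; FVA reports each
reaction's attainable flux range subject to an optional constraint on the
objective reaction.  LPs are solved with the HiGHS simplex through
scipy.optimize.linprog, which is deterministic.

Tolerances: constraint satisfaction is accepted at 1e-9 (solver epsilon);
a flux is classified "zero" (for blocked-reaction calls) below 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-6


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluxResult:
    status: str                      # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FvaResult:
    ranges: dict[str, tuple[float, float]]   # rid -> (min, max); +-inf if unbounded
    objective_id: str | None
    fraction_of_optimum: float | None


class _LpSystem:
    """Cached S matrix and bounds for repeated LP solves on one model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rids = list(model.reactions)
        self.col = {rid: j for j, rid in enumerate(self.rids)}
        mids = sorted(model.metabolites)
        row = {mid: i for i, mid in enumerate(mids)}
        data, ri, ci = [], [], []
        for rid, rxn in model.reactions.items():
            j = self.col[rid]
            for met, coef in rxn.stoich.items():
                data.append(coef)
                ri.append(row[met])
                ci.append(j)
        self.S = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(mids), len(self.rids))
        )
        self.bounds = [
            (model.reactions[rid].lb, model.reactions[rid].ub) for rid in self.rids
        ]

    def solve(self, c: np.ndarray, overrides: dict[str, tuple[float, float]] | None = None):
        bounds = self.bounds
        if overrides:
            bounds = list(bounds)
            for rid, b in overrides.items():
                bounds[self.col[rid]] = b
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=bounds,
            method="highs",
        )
        return res


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
) -> FluxResult:
    """Maximize or minimize the flux of ``objective`` (default: the
    model's biomass reaction) over the steady-state polytope."""
    if objective is None:
        objective = model.biomass_reaction_id
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    sys_ = _LpSystem(model)
    c = np.zeros(len(sys_.rids))
    c[sys_.col[objective]] = -1.0 if direction == "max" else 1.0
    res = sys_.solve(c)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxResult(status=status, objective_value=None, fluxes=None)
    fluxes = {rid: float(res.x[sys_.col[rid]]) for rid in sys_.rids}
    return FluxResult(status="optimal", objective_value=fluxes[objective], fluxes=fluxes)


def run_fva(
    model: MetabolicModel,
    objective: str | None = None,
    fraction_of_optimum: float | None = 1.0,
    reactions=None,
    objective_mode: str = "lower_bound",
) -> FvaResult:
    """Per-reaction (min, max) flux.

    If ``fraction_of_optimum`` is not None, the objective reaction is first
    optimized and then constrained: with ``objective_mode="lower_bound"``
    its flux must be >= fraction * optimum; with ``"fixed"`` it is pinned
    to exactly fraction * optimum.  With ``fraction_of_optimum=None`` no
    objective constraint is applied.  Directions that are unbounded are
    reported as +-inf.
    """
    sys_ = _LpSystem(model)
    targets = list(model.reactions) if reactions is None else list(reactions)
    for rid in targets:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction id {rid!r}")
    overrides: dict[str, tuple[float, float]] = {}
    if fraction_of_optimum is not None:
        if objective is None:
            objective = model.biomass_reaction_id
        opt = solve_fba(model, objective, "max")
        if not opt.ok:
            raise SolverError(
                f"FVA requires an optimal FBA solution; got status {opt.status}"
            )
        level = fraction_of_optimum * opt.objective_value
        rxn = model.reactions[objective]
        if objective_mode == "fixed":
            overrides[objective] = (level, level)
        elif objective_mode == "lower_bound":
            overrides[objective] = (level, rxn.ub)
        else:
            raise ValueError("objective_mode must be 'fixed' or 'lower_bound'")
    ranges: dict[str, tuple[float, float]] = {}
    n = len(sys_.rids)
    for rid in targets:
        j = sys_.col[rid]
        lohi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = sys_.solve(c, overrides)
            status = _STATUS.get(res.status, "failed")
            if status == "optimal":
                lohi.append(sign * res.fun)
            elif status == "unbounded":
                lohi.append(-math.inf if sign > 0 else math.inf)
            else:
                raise SolverError(f"FVA subproblem for {rid!r} is {status}")
        ranges[rid] = (lohi[0], lohi[1])
    return FvaResult(
        ranges=ranges,
        objective_id=objective if fraction_of_optimum is not None else None,
        fraction_of_optimum=fraction_of_optimum,
    )


def blocked_reactions(model: MetabolicModel) -> frozenset[str]:
    """Reactions that can carry no flux at all (FVA min = max = 0 with no
    objective constraint, at the zero-flux tolerance)."""
    if not model.reactions:
        return frozenset()
    fva = run_fva(model, fraction_of_optimum=None)
    return frozenset(
        rid
        for rid, (lo, hi) in fva.ranges.items()
        if abs(lo) <= ZERO_FLUX_TOL and abs(hi) <= ZERO_FLUX_TOL
    )
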