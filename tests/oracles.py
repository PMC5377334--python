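"""Independent oracles used by the tests.

These deliberately avoid the library's LP/MILP code paths: linear
programs are checked against exhaustive vertex enumeration of the flux
polytope, extraction against brute-force subset enumeration (each subset
certified by a feasibility LP built here from scratch), and gap-filling
against subset search in order of cardinality.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog

TOL = 1e-7


def _system(model, extra_eq=()):
    """Equality system A v = b for {S v = 0} plus extra rows
    (coeff-dict, rhs)."""
    rids = list(model.reactions)
    col = {rid: j for j, rid in enumerate(rids)}
    mids = sorted(model.metabolites)
    A = np.zeros((len(mids) + len(extra_eq), len(rids)))
    b = np.zeros(len(mids) + len(extra_eq))
    for i, mid in enumerate(mids):
        for rid, rxn in model.reactions.items():
            coef = rxn.stoich.get(mid)
            if coef:
                A[i, col[rid]] = coef
    for k, (coeffs, rhs) in enumerate(extra_eq):
        for rid, coef in coeffs.items():
            A[len(mids) + k, col[rid]] = coef
        b[len(mids) + k] = rhs
    lb = np.array([model.reactions[r].lb for r in rids])
    ub = np.array([model.reactions[r].ub for r in rids])
    return rids, A, b, lb, ub


def enumerate_vertices(model, extra_eq=()) -> tuple[list[str], np.ndarray]:
    """All vertices of {v : S v = 0 (+extra equalities), lb <= v <= ub}.

    A vertex fixes n - rank(A) variables at finite bounds with the rest
    solved from the equality system; only consistent, in-bounds solutions
    with a uniquely solvable basic block are kept.  Bounds must be finite
    for fixed variables (fixtures use finite bounds throughout).
    """
    rids, A, b, lb, ub = _system(model, extra_eq)
    n = len(rids)
    r = np.linalg.matrix_rank(A, tol=1e-9)
    n_fix = n - r
    vertices = []
    for fix in combinations(range(n), n_fix):
        basic = [j for j in range(n) if j not in fix]
        A_B = A[:, basic]
        if np.linalg.matrix_rank(A_B, tol=1e-9) < len(basic):
            continue
        for pattern in product((0, 1), repeat=n_fix):
            vfix = np.array(
                [lb[j] if s == 0 else ub[j] for j, s in zip(fix, pattern)]
            )
            if not np.all(np.isfinite(vfix)):
                continue
            rhs = b - A[:, fix] @ vfix
            sol, res, *_ = np.linalg.lstsq(A_B, rhs, rcond=None)
            if np.linalg.norm(A_B @ sol - rhs) > TOL:
                continue
            v = np.empty(n)
            v[list(fix)] = vfix
            v[basic] = sol
            if np.all(v >= lb - TOL) and np.all(v <= ub + TOL):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return rids, np.empty((0, n))
    V = np.unique(np.round(np.array(vertices), 9), axis=0)
    return rids, V


def fba_by_vertices(model, objective: str, direction: str = "max") -> float | None:
    """FBA optimum as the extreme objective value over all polytope
    vertices; None if the polytope is empty."""
    rids, V = enumerate_vertices(model)
    if V.shape[0] == 0:
        return None
    vals = V[:, rids.index(objective)]
    return float(vals.max() if direction == "max" else vals.min())


def fva_by_vertices(model, objective: str, fraction: float) -> dict[str, tuple[float, float]]:
    """FVA ranges with the objective pinned to fraction * optimum."""
    opt = fba_by_vertices(model, objective)
    rids, V = enumerate_vertices(model, extra_eq=[({objective: 1.0}, fraction * opt)])
    return {rid: (float(V[:, j].min()), float(V[:, j].max())) for j, rid in enumerate(rids)}


# -- extraction oracle ---------------------------------------------------

def _subset_certificate_feasible(model, subset, required, eps, big_m,
                                 soft=frozenset()) -> bool:
    """LP: does a flux vector exist in which every subset reaction carries
    |v| >= eps (forward/backward split), every required metabolite has net
    production >= eps, and soft-drain metabolites may be net-produced?"""
    sub = sorted(subset)
    col = {rid: j for j, rid in enumerate(sub)}
    mids = sorted(model.metabolites)
    req = sorted(required)
    drains = req + sorted(set(soft) - set(required))
    n = len(sub)
    nvar = 2 * n + len(drains)
    lbv = np.zeros(nvar)
    ubv = np.zeros(nvar)
    for rid in sub:
        r = model.reactions[rid]
        ubv[col[rid]] = min(max(r.ub, 0.0), big_m)
        ubv[n + col[rid]] = min(max(-r.lb, 0.0), big_m)
    for k, mid in enumerate(drains):
        lbv[2 * n + k] = eps if mid in required else 0.0
        ubv[2 * n + k] = big_m
    A_eq = np.zeros((len(mids), nvar))
    for i, mid in enumerate(mids):
        for rid in sub:
            coef = model.reactions[rid].stoich.get(mid)
            if coef:
                A_eq[i, col[rid]] = coef
                A_eq[i, n + col[rid]] = -coef
        if mid in drains:
            A_eq[i, 2 * n + drains.index(mid)] = -1.0
    A_ub = np.zeros((n, nvar))
    for rid in sub:
        A_ub[col[rid], col[rid]] = -1.0
        A_ub[col[rid], n + col[rid]] = -1.0
    res = linprog(
        np.zeros(nvar), A_ub=A_ub, b_ub=np.full(n, -eps),
        A_eq=A_eq, b_eq=np.zeros(len(mids)),
        bounds=list(zip(lbv, ubv)), method="highs",
    )
    return res.status == 0


def _task_feasible(model, subset, task, big_m=1000.0) -> bool:
    """Independent task check: boundary reactions closed, task inputs as
    sources, outputs as demands with their minimum as lower bound."""
    sub = sorted(subset)
    mids = sorted(model.metabolites)
    cols = []
    lbv, ubv = [], []
    stoich_cols = []
    for rid in sub:
        r = model.reactions[rid]
        if r.is_boundary() or rid == model.biomass_reaction_id:
            lo, hi = 0.0, 0.0
        else:
            lo, hi = max(r.lb, -big_m), min(r.ub, big_m)
        cols.append(rid)
        lbv.append(lo)
        ubv.append(hi)
        stoich_cols.append(r.stoich)
    for met, cap in task.inputs.items():
        cols.append(f"in_{met}")
        lbv.append(0.0)
        ubv.append(cap)
        stoich_cols.append({met: 1.0})
    for met, minimum in task.outputs.items():
        cols.append(f"out_{met}")
        lbv.append(minimum)
        ubv.append(big_m)
        stoich_cols.append({met: -1.0})
    A_eq = np.zeros((len(mids), len(cols)))
    for j, st in enumerate(stoich_cols):
        for met, coef in st.items():
            if met in model.metabolites:
                A_eq[mids.index(met), j] = coef
    res = linprog(
        np.zeros(len(cols)), A_eq=A_eq, b_eq=np.zeros(len(mids)),
        bounds=list(zip(lbv, ubv)), method="highs",
    )
    return res.status == 0


def best_subsets_by_enumeration(model, weights, required=frozenset(), tasks=(),
                                eps=1e-4, big_m=1000.0):
    """Exhaustive search over all reaction subsets.

    Returns (best objective, list of optimal subsets) under the same
    semantics as the extraction MILP: certificate feasibility, required
    net production, every non-should_fail task passes and every
    should_fail task fails on the subset.
    """
    rids = list(model.reactions)
    soft = frozenset(
        m for t in tasks for m in t.outputs if m in model.metabolites
    )
    best_obj, best_sets = -np.inf, []
    for mask in range(2 ** len(rids)):
        subset = frozenset(rid for j, rid in enumerate(rids) if mask >> j & 1)
        if not _subset_certificate_feasible(model, subset, required, eps, big_m,
                                            soft=soft):
            continue
        ok = True
        for task in tasks:
            passed = _task_feasible(model, subset, task)
            if passed == bool(task.should_fail):
                ok = False
                break
        if not ok:
            continue
        obj = sum(weights[rid] for rid in subset)
        if obj > best_obj + 1e-9:
            best_obj, best_sets = obj, [subset]
        elif abs(obj - best_obj) <= 1e-9:
            best_sets.append(subset)
    return best_obj, best_sets


# -- gap-fill oracle -----------------------------------------------------

def _growth_lp(model, subset, min_growth) -> bool:
    sub = sorted(subset)
    col = {rid: j for j, rid in enumerate(sub)}
    mids = sorted(model.metabolites)
    lbv = np.array([model.reactions[r].lb for r in sub])
    ubv = np.array([model.reactions[r].ub for r in sub])
    if model.biomass_reaction_id not in col:
        return False
    lbv[col[model.biomass_reaction_id]] = max(
        lbv[col[model.biomass_reaction_id]], min_growth
    )
    A_eq = np.zeros((len(mids), len(sub)))
    for i, mid in enumerate(mids):
        for rid in sub:
            coef = model.reactions[rid].stoich.get(mid)
            if coef:
                A_eq[i, col[rid]] = coef
    res = linprog(
        np.zeros(len(sub)), A_eq=A_eq, b_eq=np.zeros(len(mids)),
        bounds=list(zip(lbv, ubv)), method="highs",
    )
    return res.status == 0


def min_gapfill_by_enumeration(model, universal, min_growth):
    """Smallest number of universal-only reactions whose addition reaches
    the growth target; None if no subset works."""
    base = set(model.reactions)
    candidates = [rid for rid in universal.reactions if rid not in base]
    for k in range(len(candidates) + 1):
        for combo in combinations(candidates, k):
            if _growth_lp(universal, base | set(combo), min_growth):
                return k, set(combo)
    return None, None
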