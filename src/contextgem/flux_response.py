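"""Flux response analysis: growth-coupled reaction identification.

The biomass reaction is forced step-by-step through a range of fractions
of its maximal rate (default 90%..100% in 11 steps).  At each step an FVA
gives every reaction's attainable (min, max) flux; the midpoint
(min+max)/2 is taken as that reaction's mean flux.  A reaction whose mean
flux rises with the enforced growth rate is growth-coupled; coupling is
quantified by the Pearson correlation r between the reaction's mean-flux
series and the biomass flux series, and reactions with r strictly greater
than 0.7 are called growth-associated.  A constant mean-flux series has
zero variance and is assigned r = 0 (constant flux cannot evidence
coupling).  The threshold is applied to signed r: anti-correlated
reactions (competing routes, uptake exchanges) are not growth-associated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lp import run_fva, solve_fba
from .model import MetabolicModel

DEFAULT_FRACTIONS = tuple(np.linspace(0.90, 1.00, 11))
R_THRESHOLD = 0.7


class FluxResponseError(RuntimeError):
    pass


@dataclass
class GrowthAssociationResult:
    fractions: tuple[float, ...]
    mu_max: float
    mean_flux: pd.DataFrame           # index reaction, one column per fraction
    biomass_series: np.ndarray        # enforced biomass flux per fraction
    correlations: pd.Series           # reaction -> Pearson r (0 for constant series)
    mode: str


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def flux_response_scan(
    model: MetabolicModel,
    fractions=DEFAULT_FRACTIONS,
    mode: str = "fixed",
) -> GrowthAssociationResult:
    """Scan enforced biomass levels and correlate mean fluxes with growth.

    ``mode="fixed"`` pins biomass flux to fraction * mu_max at each step
    (the default reading of forcing the growth rate); ``"lower_bound"``
    only bounds it from below.
    """
    fractions = tuple(float(f) for f in fractions)
    if not fractions or any(f < 0 or f > 1 for f in fractions):
        raise FluxResponseError("fractions must lie within [0, 1]")
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise FluxResponseError("fractions must be strictly increasing")
    if mode not in ("fixed", "lower_bound"):
        raise FluxResponseError("mode must be 'fixed' or 'lower_bound'")
    opt = solve_fba(model)
    if not opt.ok or opt.objective_value <= 0:
        raise FluxResponseError("no growth; gap-fill first")
    mu_max = opt.objective_value

    rids = list(model.reactions)
    series = np.empty((len(rids), len(fractions)))
    for k, f in enumerate(fractions):
        try:
            fva = run_fva(
                model,
                objective=model.biomass_reaction_id,
                fraction_of_optimum=f,
                objective_mode="fixed" if mode == "fixed" else "lower_bound",
            )
        except Exception as exc:
            raise FluxResponseError(f"infeasible scan step at fraction {f}") from exc
        for i, rid in enumerate(rids):
            lo, hi = fva.ranges[rid]
            series[i, k] = 0.5 * (lo + hi)
    biomass = mu_max * np.asarray(fractions)
    corr = pd.Series(
        [_pearson(series[i], biomass) for i in range(len(rids))],
        index=rids, name="pearson_r",
    )
    mean_flux = pd.DataFrame(series, index=rids, columns=[f"{f:.6g}" for f in fractions])
    mean_flux.index.name = "reaction"
    return GrowthAssociationResult(
        fractions=fractions,
        mu_max=mu_max,
        mean_flux=mean_flux,
        biomass_series=biomass,
        correlations=corr,
        mode=mode,
    )


def growth_associated_reactions(
    result: GrowthAssociationResult, r_threshold: float = R_THRESHOLD
) -> frozenset[str]:
    """Reactions whose mean-flux series correlates with biomass at
    r strictly greater than the threshold (signed, not absolute)."""
    return frozenset(result.correlations.index[result.correlations > r_threshold])


def write_growth_association(result: GrowthAssociationResult, path) -> None:
    """TSV: reaction, pearson_r, mean flux at each fraction; the fraction
    grid and scan mode are echoed in a header comment line."""
    with open(path, "w") as fh:
        fh.write(
            "# fractions=" + ",".join(f"{f:.6g}" for f in result.fractions)
            + f" mode={result.mode} mu_max={result.mu_max:.10g}\n"
        )
        out = result.mean_flux.copy()
        out.insert(0, "pearson_r", result.correlations)
        out.to_csv(fh, sep="\t")
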