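# Methods

This note records the models, parameter choices and numerical decisions
behind `contextgem`, and what the synthetic studies do and do not show.

## Constraint-based modelling layer

A metabolic model is a stoichiometric matrix S with per-reaction flux
bounds, GPR rules and a designated biomass reaction. Exchange reactions
are single-metabolite boundary reactions written as `met →`, so positive
flux is secretion and negative flux is uptake; applying a medium sets
each exchange's lower bound to −(maximum uptake) and closes uptake for
exchanges the medium omits. Reversibility is encoded purely by a
negative lower bound. Flux balance analysis maximizes (or minimizes) a
single reaction's flux over {v : S v = 0, lb ≤ v ≤ ub}; flux variability
analysis solves 2N such LPs with the objective reaction either bounded
below by, or pinned to, a fraction of its optimum. All LPs use the HiGHS
solver via SciPy, which is deterministic. Constraint satisfaction is
accepted at 1e−9; fluxes below 1e−6 in magnitude are classified as zero
(blocked-reaction calls). Unbounded FVA directions are reported as ±inf
rather than as errors, since open exchange bounds are common.

The test suite certifies this layer against exhaustive vertex
enumeration of the flux polytope on all fixture models (≤8 reactions)
and cross-checks FBA values against COBRApy's GLPK-backed solver.

## Differential expression

Two-sample equal-variance Student's t-test per gene on duplicate
profiles, with calls gated by raw P < 0.05 *and* linear fold change
mean(A)/mean(B) > 1.5 (up) or < 1/1.5 (down). Benjamini–Hochberg values
are emitted for information but never gate calls. The t-test operates on
log2 intensities: microarray intensities are approximately lognormal,
log2 transformation is what standard microarray DE tools apply before
testing, and with n = 2 per group the pooled-variance test on the log
scale is both the homoscedastic and the substantially better-powered
reading. Fold changes remain ratios of linear-scale means. Degenerate
genes (zero variance in both groups) get p = 1 when the means are equal
and p = 0 otherwise. Ranking for gene scores uses mean expression per
sample group of interest; ties are broken by gene id so fixture results
are stable.

## Gene scores and reaction weights

Genes are ranked ascending by expression (highest expression → rank N)
and scored rank/(0.3 N): the 0.3 makes the 30th percentile the neutral
pivot (score exactly 1). Reaction weights fold scores through the GPR —
max over OR branches, min over AND branches — and subtract 1, so
below-pivot genes discourage inclusion of their reactions. Reactions
without gene association get weight 0 (orphan reactions are
weight-neutral); genes without a score default to the pivot value.

## Context extraction

Extraction is a single-certificate INIT-style MILP: binary inclusion
y_r per reaction maximizes Σ w_r y_r subject to

* a flux vector v (reversible reactions split into nonnegative forward
  and backward parts) with ε·y_r ≤ v⁺_r + v⁻_r ≤ M·y_r, ε = 1e−4 and
  big-M = 1000 in flux units;
* steady-state mass balance relaxed by a production slack ≥ ε for every
  *required* metabolite (those detected in the metabolome and mapped
  into the model), certifying net intracellular production;
* a nonnegative (no-minimum) production slack for every metabolite that
  appears as a metabolic-task output. Without this, a reaction whose
  product is consumed only inside a task environment could never carry
  certificate flux and thus could never be included, contradicting the
  task constraints below;
* every positive task passes and every negative-control (`should_fail`)
  task fails on the extracted subnetwork.

Tasks are enforced by iterative cut generation rather than one
monolithic MILP: solve, check tasks on the selected subnetwork, add a
cover cut per violated task, repeat. For a failing positive task the cut
requires including at least one currently-excluded reaction from the
task's *support* (the reactions able to carry flux in the task
environment on the full universal network) — valid because task passing
is monotone in the reaction set and any passing subnetwork draws on the
support. For a passing negative-control task the cut requires dropping
at least one reaction active in the offending flux solution. Each cut
excludes the current incumbent, so the loop terminates (bounded at 50
iterations) at the constrained optimum. A metabolic task itself is
checked by closing *all* boundary reactions (including the biomass
drain), installing temporary sources for the task's allowed inputs and
temporary demands (lower-bounded by the required minimum) for its
outputs, and testing LP feasibility.

The MILP is solved with HiGHS; variable order is fixed by model order,
so identical inputs give identical extractions. The certificate model
may legitimately omit the biomass reaction (growth is restored by
gap-filling); a deterministic placeholder keeps the subnetwork a valid
model object. Brute-force subset enumeration (with an independently
written LP feasibility check mirroring the same certificate semantics)
certifies both the objective and the selected set on small universes.

## Gap-filling

Given a context model, its universal parent and a medium, a MILP adds
binary indicators for universal-only reactions, couples them to flux
big-M constraints, requires biomass flux ≥ a growth floor (default
1e−3 flux units — "demonstrates growth" without prescribing a rate) and
minimizes the number of additions. When even the combined network cannot
reach the floor, the error names the biomass precursors that cannot be
net-produced. Subset search in order of cardinality certifies minimality
on small instances.

## Flux response analysis

With μ_max from FBA, the biomass flux is constrained at each fraction f
of μ_max — pinned (`fixed`, the default: the growth rate is *forced*)
or bounded below (`lower_bound`, kept for sensitivity analysis) — and a
full FVA is run per step. The default grid is 11 evenly spaced fractions
from 0.90 to 1.00; the range is part of the method, the step count is a
project choice and is echoed in the output metadata, and on
linear-response networks doubling it changes no correlation
perceptibly. A reaction's mean flux at a step is the midpoint
(min+max)/2 of its FVA range — the only computable reading of a mean
from range data. Pearson r is computed between each mean-flux series
and the enforced biomass series; a zero-variance series gets r = 0
(constant attainable flux cannot evidence growth coupling) rather than
an undefined value. Growth association uses the *signed*, strict
threshold r > 0.7: anti-correlated reactions (competing routes, uptake
exchanges, whose flux grows more negative) are not growth-associated.

## TF ranking

Growth-associated reactions map to genes via GPR union. TFs from a
(TF, target, confidence, evidence) edge table — filtered to
high-confidence rows, duplicate edges collapsed — are ranked by
|targets ∩ growth-associated genes|, descending, ties broken by TF id.
This is a raw target count, not an enrichment statistic, matching the
replicated procedure; TFs with zero overlap are excluded from the
ranking (available via a diagnostic flag). Gene identifiers must share a
namespace between GPRs and the network file; a synonym table is accepted
but no automatic identifier conversion is attempted.

## Synthetic studies

The generator emulates the study design at toy scale with planted ground
truth. Defaults (all exposed on `SyntheticSpec`):

| parameter | default | meaning |
|---|---|---|
| `n_coupled_pathway_length` | 6 | reactions in the linear biomass chain |
| `n_decoy_reactions` | 4 | bounded nutrient conversions independent of growth |
| `n_genes` | 240 | gene pool (≥200 nulls after planting) |
| `n_planted_up_genes` / `n_planted_down_genes` | 20 / 10 | 2-fold effects in the stem-like group |
| `effect_size` | 2.0 | planted fold effect |
| `noise_sd` | 0.1 | lognormal σ per replicate measurement |
| `replicates` | 2 | duplicate profiles per group |
| `n_tfs` | 6 | one master + decoy TFs |
| `master_tf_coverage` | 1.0 | fraction of pathway genes the master targets |

The universal model couples one linear pathway (uptake 10 mmol gDW⁻¹h⁻¹
→ chain → biomass precursor → biomass) to growth, and gives each decoy
an independent capped nutrient (5 units) so its conversion has constant
attainable flux at any growth rate. Pathway reactions carry GPRs over
the first planted-up genes (one reaction is a two-gene complex); decoys
carry null-pool genes. The metabolome plants fold changes on two chain
intermediates and realizes every detection category (both / one type
only / neither / irreproducible) through a deterministic dropout map.
The regulatory network gives the master TF exactly the pathway genes and
decoy TFs only decoy genes, all edges high-confidence.

Multiplicative lognormal noise mimics microarray intensity behaviour but
not probe effects, batch structure, or correlated genes; the toy model
has none of a real GEM's compartment structure, cofactor coupling or
thousands of alternative routes. Passing tests therefore demonstrate
correctness of the algorithms and exact recovery under the planted
conditions, not performance on genome-scale data. Bundles stay under
~100 reactions by design; genome-scale extraction would need a
commercial-grade MILP time budget.

## Pipeline

Stages run in order DE → scoring (per replicate sample, metabolic genes
only, mirroring the per-replicate reconstruction of the study design) →
extraction per sample (required production from that sample's cell-type
detection) → gap-fill → flux response on the stem-like group's models →
TF ranking on the union of their growth-associated genes. All thresholds
default to the replicated parameters (P 0.05, FC 1.5, rank fraction 0.3,
r 0.7, scan 0.90–1.00 in 11 steps). Stage outputs are cached with
content hashes; unchanged inputs skip completed stages and forced reruns
reproduce byte-identical outputs. The acceptance script sizes everything
to 20 seeded studies and ≤12-reaction oracle fixtures, which keeps a
full reproduction around two minutes on one CPU.

## Known limitations

* The extraction MILP uses one certifying flux vector (simplified from
  task-driven network inference as published); reactions active only in
  mutually exclusive flux modes may be over- or under-selected relative
  to the full formulation.
* A reversible reaction can satisfy its activity constraint with
  balanced forward+backward parts (zero net flux); at toy scale this
  does not arise, but on genome-scale networks loop-law constraints
  would be needed.
* Fold changes assume linear-scale intensities with no normalization
  step; inputs are expected pre-normalized.
* No statistical enrichment test backs the TF ranking — it is a raw
  target count by design.
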