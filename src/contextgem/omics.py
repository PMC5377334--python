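"""Transcriptome and metabolome processing.

Differential expression follows the study design this pipeline targets:
duplicate microarray profiles per cell type, a two-sample equal-variance
Student's t-test per gene (computed on log2 intensities, the standard
scale for microarray testing) with a raw P < 0.05 gate, and a linear
fold-change gate of > 1.5 (or < 1/1.5 for down-calls).  No multiple
testing correction gates the calls; a Benjamini-Hochberg column is
emitted for information only.

Gene scoring for context-specific model extraction ranks genes by
expression (highest expression -> rank N) and sets
``score = rank / (0.3 * N)``, so a gene at the 30th percentile scores
exactly 1; genes in the bottom 30% score below 1.

Metabolome tables carry per-replicate concentrations for two cell types,
with empty cells meaning "not detected".  Metabolites are classified by
detection pattern (both / one type only / neither / irreproducible) and,
for those detected in both types, by linear fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class OmicsValidationError(ValueError):
    pass


# -- expression ----------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene x sample intensities plus a sample -> group labelling."""

    values: pd.DataFrame              # index: gene id, columns: sample id
    groups: dict[str, str]            # sample id -> group label

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise OmicsValidationError(f"samples without group label: {missing}")
        if self.values.isna().any().any():
            raise OmicsValidationError("expression table contains missing values")

    def samples_of(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == group]
        if not cols:
            raise OmicsValidationError(f"no samples labelled {group!r}")
        return cols


def read_expression(values_path, groups_path) -> ExpressionTable:
    """Expression TSV (first column gene id, rest samples) plus a
    two-column TSV mapping sample -> group."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return ExpressionTable(values=values, groups=groups)


def differential_expression(
    expr: ExpressionTable,
    group_a: str,
    group_b: str,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-gene t-test and fold change between two groups.

    Returns a DataFrame indexed by gene with columns ``fold_change``
    (mean(A)/mean(B), linear scale), ``p_value``, ``p_adj`` (BH,
    informational only) and ``call`` in {up, down, ns}.  A gene is "up"
    iff p < p_threshold and FC > fc_threshold, "down" iff p < p_threshold
    and FC < 1/fc_threshold.
    """
    cols_a = expr.samples_of(group_a)
    cols_b = expr.samples_of(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise OmicsValidationError("need >=2 samples per group for a t-test")
    a = expr.values[cols_a].to_numpy(float)
    b = expr.values[cols_b].to_numpy(float)
    if (a <= 0).any() or (b <= 0).any():
        raise OmicsValidationError("intensities must be positive")

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a harmless precision warning inside scipy;
        # the degenerate p-values are overwritten below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(np.log2(a), np.log2(b), axis=1, equal_var=True)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # degenerate: zero variance in both groups -> p undefined by the test;
    # equal means is evidence of nothing (p=1), unequal means is exact (p=0)
    degen = np.isnan(p)
    p = np.where(degen, np.where(np.isclose(mean_a, mean_b), 1.0, 0.0), p)

    fc = mean_a / mean_b
    call = np.full(len(fc), "ns", dtype=object)
    call[(p < p_threshold) & (fc > fc_threshold)] = "up"
    call[(p < p_threshold) & (fc < 1.0 / fc_threshold)] = "down"
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "p_adj": _benjamini_hochberg(p),
            "call": call,
        },
        index=expr.values.index,
    )
    out.index.name = "gene"
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# -- gene scoring --------------------------------------------------------

@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene rank (1..N, N = highest expression) and score
    rank/(fraction*N)."""

    table: pd.DataFrame               # index gene, columns rank, score
    fraction: float = 0.3

    def score_of(self, gene: str, default: float = 1.0) -> float:
        try:
            return float(self.table.at[gene, "score"])
        except KeyError:
            return default


def rank_gene_scores(
    expression: pd.Series | dict[str, float], fraction: float = 0.3
) -> GeneScoreTable:
    """Rank genes ascending by summary expression (ties broken by gene id,
    stable) and score each as rank/(fraction*N)."""
    if isinstance(expression, dict):
        expression = pd.Series(expression, dtype=float)
    if len(expression) == 0:
        raise OmicsValidationError("cannot rank an empty expression vector")
    ordered = expression.sort_index(kind="stable").sort_values(kind="stable")
    n = len(ordered)
    ranks = pd.Series(np.arange(1, n + 1), index=ordered.index)
    scores = ranks / (fraction * n)
    table = pd.DataFrame({"rank": ranks, "score": scores}).loc[expression.index]
    table.index.name = "gene"
    return GeneScoreTable(table=table, fraction=fraction)


# -- metabolome ----------------------------------------------------------

@dataclass
class MetabolomeTable:
    """Metabolite x replicate concentrations for two cell types.

    ``values`` columns are named ``<type>_<rep>``; NaN means the
    metabolite was not detected in that replicate.  ``classes`` labels
    each metabolite "standard" (absolute pmol/1e6 cells) or "putative"
    (relative peak area).
    """

    values: pd.DataFrame
    classes: pd.Series                # metabolite -> standard|putative

    def type_columns(self, cell_type: str) -> list[str]:
        cols = [c for c in self.values.columns if c.rsplit("_", 1)[0] == cell_type]
        if not cols:
            raise OmicsValidationError(f"no replicate columns for cell type {cell_type!r}")
        return cols


def read_metabolome(path) -> MetabolomeTable:
    """TSV: metabolite, class, then replicate columns named <type>_<rep>;
    empty cell = not detected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "class" not in df.columns:
        raise OmicsValidationError("metabolome file needs a 'class' column")
    classes = df["class"].astype(str)
    values = df.drop(columns=["class"]).astype(float)
    return MetabolomeTable(values=values, classes=classes)


DETECTION_CATEGORIES = ("both", "A_only", "B_only", "neither", "irreproducible")


def classify_detection(
    metabolome: MetabolomeTable, type_a: str, type_b: str
) -> pd.DataFrame:
    """Detection category per metabolite.

    "both": detected in every replicate of both types; "A_only"/"B_only":
    detected in every replicate of exactly one type and none of the other;
    "neither": no replicate at all; anything else is "irreproducible".
    The categories partition the metabolite set.
    """
    cols_a = metabolome.type_columns(type_a)
    cols_b = metabolome.type_columns(type_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise OmicsValidationError("need >=2 replicates per cell type")
    det = metabolome.values.notna()
    all_a, any_a = det[cols_a].all(axis=1), det[cols_a].any(axis=1)
    all_b, any_b = det[cols_b].all(axis=1), det[cols_b].any(axis=1)
    category = pd.Series("irreproducible", index=metabolome.values.index, dtype=object)
    category[all_a & all_b] = "both"
    category[all_a & ~any_b] = "A_only"
    category[all_b & ~any_a] = "B_only"
    category[~any_a & ~any_b] = "neither"
    out = pd.DataFrame({"category": category})
    out.index.name = "metabolite"
    return out


def metabolite_fold_changes(
    metabolome: MetabolomeTable,
    type_a: str,
    type_b: str,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Linear fold change mean(A)/mean(B) for metabolites detected in both
    cell types; others are excluded with their detection category as the
    reason.  ``flagged`` is True iff FC > threshold or FC < 1/threshold."""
    detection = classify_detection(metabolome, type_a, type_b)
    cols_a = metabolome.type_columns(type_a)
    cols_b = metabolome.type_columns(type_b)
    rows = []
    for met, cat in detection["category"].items():
        if cat != "both":
            rows.append((met, np.nan, False, f"excluded: {cat}"))
            continue
        mean_a = metabolome.values.loc[met, cols_a].mean()
        mean_b = metabolome.values.loc[met, cols_b].mean()
        fc = mean_a / mean_b
        flagged = bool(fc > fc_threshold or fc < 1.0 / fc_threshold)
        rows.append((met, fc, flagged, ""))
    out = pd.DataFrame(
        rows, columns=["metabolite", "fold_change", "flagged", "reason"]
    ).set_index("metabolite")
    return out


def production_targets(
    metabolome: MetabolomeTable,
    model,
    synonym_table: dict[str, str] | None = None,
    type_a: str | None = None,
    type_b: str | None = None,
) -> tuple[frozenset[str], list[str]]:
    """Map detected metabolites to model metabolite ids.

    A metabolite counts as detected if any replicate detected it (or, when
    ``type_a``/``type_b`` are given, if it is not in the "neither"
    category).  Returns (matched model ids, unmatched names); unmatched
    names are reported, never silently dropped.
    """
    synonym_table = synonym_table or {}
    det = metabolome.values.notna()
    detected = [m for m in metabolome.values.index if det.loc[m].any()]
    matched: set[str] = set()
    unmatched: list[str] = []
    for name in detected:
        target = synonym_table.get(name, name if name in model.metabolites else None)
        if target is not None and target in model.metabolites:
            matched.add(target)
        else:
            unmatched.append(name)
    return frozenset(matched), unmatched


def read_synonyms(path) -> dict[str, str]:
    """Two-column TSV: metabolite name, model metabolite id."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
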