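"""End-to-end pipeline: DE -> gene scoring -> per-sample model extraction
-> gap-filling -> flux response -> TF ranking.

The pipeline is driven by a flat INI config (sections below) whose
defaults mirror the study parameters this package replicates: raw t-test
P < 0.05 with linear fold change > 1.5 for differential expression, gene
score rank/(0.3 N), biomass scan from 90% to 100% of the optimum in 11
steps, Pearson r > 0.7 for growth association, and High-confidence
regulatory edges.

Stage outputs are written to the output directory and cached: re-running
with unchanged inputs and config skips completed stages (the manifest
records an input hash per stage); identical config and inputs give
byte-identical outputs.

Config schema::

    [paths]      model expression groups metabolome synonyms network
                 medium tasks
    [design]     group_a group_b confidence
    [thresholds] p fc rank_fraction r
    [scan]       start stop steps mode
    [extraction] epsilon big_m min_growth
    [output]     dir
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .extraction import (
    BIG_M,
    DEFAULT_MIN_GROWTH,
    EPSILON,
    extract_context_model,
    gapfill_growth,
    reaction_weights,
    read_tasks,
)
from .flux_response import (
    flux_response_scan,
    growth_associated_reactions,
    write_growth_association,
)
from .model import (
    apply_medium,
    genes_of_reactions,
    read_medium,
    read_model,
    write_model,
)
from .omics import (
    classify_detection,
    differential_expression,
    rank_gene_scores,
    read_expression,
    read_metabolome,
    read_synonyms,
)
from .tf_rank import load_regulatory_network, rank_transcription_factors, write_tf_ranking

logger = logging.getLogger("contextgem")


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, dict[str, str]] = {
    "paths": {
        "model": "", "expression": "", "groups": "", "metabolome": "",
        "synonyms": "", "network": "", "medium": "", "tasks": "",
    },
    "design": {"group_a": "LCSC", "group_b": "nonLCSC", "confidence": "High"},
    "thresholds": {"p": "0.05", "fc": "1.5", "rank_fraction": "0.3", "r": "0.7"},
    "scan": {"start": "0.90", "stop": "1.00", "steps": "11", "mode": "fixed"},
    "extraction": {
        "epsilon": str(EPSILON), "big_m": str(BIG_M),
        "min_growth": str(DEFAULT_MIN_GROWTH),
    },
    "output": {"dir": ""},
}


@dataclass
class PipelineConfig:
    paths: dict[str, str]
    group_a: str = "LCSC"
    group_b: str = "nonLCSC"
    confidence: str = "High"
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    rank_fraction: float = 0.3
    r_threshold: float = 0.7
    scan_start: float = 0.90
    scan_stop: float = 1.00
    scan_steps: int = 11
    scan_mode: str = "fixed"
    epsilon: float = EPSILON
    big_m: float = BIG_M
    min_growth: float = DEFAULT_MIN_GROWTH
    outdir: str = "pipeline_out"

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p threshold must be in (0,1)")
        if self.fc_threshold <= 1:
            raise ConfigError("fc threshold must exceed 1")
        if not 0 < self.rank_fraction <= 1:
            raise ConfigError("rank_fraction must be in (0,1]")
        if not -1 <= self.r_threshold <= 1:
            raise ConfigError("r threshold must be in [-1,1]")
        if not (0 <= self.scan_start < self.scan_stop <= 1) or self.scan_steps < 2:
            raise ConfigError("scan range must satisfy 0<=start<stop<=1, steps>=2")

    @property
    def fractions(self) -> list[float]:
        step = (self.scan_stop - self.scan_start) / (self.scan_steps - 1)
        return [self.scan_start + i * step for i in range(self.scan_steps)]

    @classmethod
    def from_ini(cls, path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ConfigError(f"config file not found: {path}")
        merged: dict[str, dict[str, str]] = {}
        for section in parser.sections():
            if section not in _SCHEMA:
                raise ConfigError(f"unknown config section [{section}]")
            merged[section] = {}
            for key, value in parser.items(section):
                if key not in _SCHEMA[section]:
                    raise ConfigError(f"unknown config key {key!r} in [{section}]")
                merged[section][key] = value

        def get(section, key):
            return merged.get(section, {}).get(key, _SCHEMA[section][key])

        paths = {k: get("paths", k) for k in _SCHEMA["paths"]}
        missing = [k for k, v in paths.items() if not v]
        if missing:
            raise ConfigError(f"missing required paths in config: {missing}")
        return cls(
            paths=paths,
            group_a=get("design", "group_a"),
            group_b=get("design", "group_b"),
            confidence=get("design", "confidence"),
            p_threshold=float(get("thresholds", "p")),
            fc_threshold=float(get("thresholds", "fc")),
            rank_fraction=float(get("thresholds", "rank_fraction")),
            r_threshold=float(get("thresholds", "r")),
            scan_start=float(get("scan", "start")),
            scan_stop=float(get("scan", "stop")),
            scan_steps=int(get("scan", "steps")),
            scan_mode=get("scan", "mode"),
            epsilon=float(get("extraction", "epsilon")),
            big_m=float(get("extraction", "big_m")),
            min_growth=float(get("extraction", "min_growth")),
            outdir=get("output", "dir") or "pipeline_out",
        )

    def validate_inputs(self) -> None:
        missing = [f"{k}: {v}" for k, v in self.paths.items() if not Path(v).exists()]
        if missing:
            raise ConfigError("input files not found -- " + "; ".join(missing))


@dataclass
class PipelineReport:
    config: PipelineConfig
    de_table: pd.DataFrame
    gene_scores: dict[str, pd.DataFrame]          # sample -> score table
    extraction: dict[str, dict]                   # sample -> summary
    gapfill: dict[str, dict]
    growth_associated: dict[str, list[str]]       # group-A sample -> reactions
    growth_genes: list[str]
    tf_ranking: pd.DataFrame
    cached_stages: list[str] = field(default_factory=list)


def _hash_files(*paths, extra: str = "") -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    h.update(extra.encode())
    return h.hexdigest()


class _StageCache:
    def __init__(self, outdir: Path, force: bool):
        self.manifest_path = outdir / "manifest.json"
        self.force = force
        self.entries: dict[str, str] = {}
        self.previous: dict[str, str] = {}
        if self.manifest_path.exists() and not force:
            try:
                self.previous = json.loads(self.manifest_path.read_text()).get(
                    "stages", {}
                )
            except json.JSONDecodeError:
                self.previous = {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        self.entries[stage] = key
        return (
            not self.force
            and self.previous.get(stage) == key
            and all(p.exists() for p in outputs)
        )

    def write(self, config: PipelineConfig) -> None:
        manifest = {
            "tool": "contextgem",
            "version": __version__,
            "config": {**asdict(config)},
            "stages": self.entries,
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, force: bool = False) -> PipelineReport:
    """Execute all stages in order, reusing cached stage outputs where the
    inputs are unchanged.  Identical config + inputs give identical
    reports."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(outdir, force)
    cached: list[str] = []
    p = config.paths

    fmt = "sbml" if p["model"].endswith((".xml", ".sbml")) else "json"
    universal = read_model(p["model"], fmt)
    medium = read_medium(p["medium"])
    tasks = read_tasks(p["tasks"])
    expr = read_expression(p["expression"], p["groups"])
    metabolome = read_metabolome(p["metabolome"])
    synonyms = read_synonyms(p["synonyms"])

    # --- stage: differential expression --------------------------------
    de_path = outdir / "de.tsv"
    de_key = _hash_files(
        p["expression"], p["groups"],
        extra=f"{config.group_a}|{config.group_b}|{config.p_threshold}|{config.fc_threshold}",
    )
    if cache.fresh("de", de_key, [de_path]):
        de_table = pd.read_csv(de_path, sep="\t", index_col=0)
        cached.append("de")
        logger.info("stage de: cached")
    else:
        de_table = differential_expression(
            expr, config.group_a, config.group_b,
            config.p_threshold, config.fc_threshold,
        )
        de_table.to_csv(de_path, sep="\t")
        logger.info("stage de: %d up, %d down",
                    (de_table["call"] == "up").sum(), (de_table["call"] == "down").sum())

    # --- stage: gene scoring (per replicate sample, metabolic genes) ---
    model_genes = sorted(universal.genes)
    samples = list(expr.values.columns)
    scores: dict[str, pd.DataFrame] = {}
    score_key = _hash_files(
        p["expression"], p["groups"], p["model"], extra=str(config.rank_fraction)
    )
    score_paths = {s: outdir / f"scores_{s}.tsv" for s in samples}
    if cache.fresh("score", score_key, list(score_paths.values())):
        for s in samples:
            scores[s] = pd.read_csv(score_paths[s], sep="\t", index_col=0)
        cached.append("score")
        logger.info("stage score: cached")
    else:
        for s in samples:
            table = rank_gene_scores(
                expr.values.loc[expr.values.index.isin(model_genes), s],
                config.rank_fraction,
            ).table
            table.to_csv(score_paths[s], sep="\t")
            scores[s] = table

    # --- required production per cell type -----------------------------
    detection = classify_detection(metabolome, config.group_a, config.group_b)
    required: dict[str, frozenset[str]] = {}
    for group, own_cat in ((config.group_a, "A_only"), (config.group_b, "B_only")):
        names = detection.index[detection["category"].isin(["both", own_cat])]
        required[group] = frozenset(
            synonyms[n] for n in names
            if n in synonyms and synonyms[n] in universal.metabolites
        )

    # --- stage: per-sample extraction + gap-fill -----------------------
    extraction_summary: dict[str, dict] = {}
    gapfill_summary: dict[str, dict] = {}
    extract_key = _hash_files(
        p["model"], p["metabolome"], p["synonyms"], p["medium"], p["tasks"],
        extra=score_key + f"|{config.epsilon}|{config.big_m}|{config.min_growth}",
    )
    model_paths = {s: outdir / f"model_{s}.json" for s in samples}
    summary_path = outdir / "extraction.json"
    if cache.fresh("extract", extract_key, list(model_paths.values()) + [summary_path]):
        stored = json.loads(summary_path.read_text())
        extraction_summary = stored["extraction"]
        gapfill_summary = stored["gapfill"]
        cached.append("extract")
        logger.info("stage extract: cached")
    else:
        for s in samples:
            group = expr.groups[s]
            score_table = scores[s]
            weights = reaction_weights(
                universal,
                {g: float(v) for g, v in score_table["score"].items()},
            )
            result = extract_context_model(
                universal, weights,
                required_production=required[group],
                tasks=tasks, medium=medium,
                epsilon=config.epsilon, big_m=config.big_m,
            )
            gap = gapfill_growth(
                result.model, universal, medium, min_growth=config.min_growth
            )
            final = apply_medium(
                universal.subset(set(result.kept) | set(gap.added)), medium
            )
            write_model(final, model_paths[s], "json")
            extraction_summary[s] = {
                "group": group,
                "kept": sorted(result.kept),
                "dropped": sorted(result.dropped),
                "objective": result.objective_value,
                "task_violations": [
                    t for t, r in result.task_report.items() if r["violation"]
                ],
            }
            gapfill_summary[s] = {"added": gap.added, "growth": gap.growth}
            logger.info(
                "stage extract[%s]: kept %d/%d reactions, gap-filled %d, growth %.4g",
                s, len(result.kept), len(universal.reactions), len(gap.added), gap.growth,
            )
        summary_path.write_text(json.dumps(
            {"extraction": extraction_summary, "gapfill": gapfill_summary},
            indent=1, sort_keys=True,
        ) + "\n")

    # --- stage: flux response on group-A models ------------------------
    a_samples = [s for s in samples if expr.groups[s] == config.group_a]
    growth_assoc: dict[str, list[str]] = {}
    scan_key = extract_key + f"|{config.fractions}|{config.scan_mode}|{config.r_threshold}"
    scan_paths = {s: outdir / f"growth_association_{s}.tsv" for s in a_samples}
    assoc_path = outdir / "growth_associated.json"
    if cache.fresh("fluxresponse", scan_key, list(scan_paths.values()) + [assoc_path]):
        growth_assoc = json.loads(assoc_path.read_text())
        cached.append("fluxresponse")
        logger.info("stage fluxresponse: cached")
    else:
        for s in a_samples:
            m = read_model(model_paths[s], "json")
            result = flux_response_scan(m, config.fractions, config.scan_mode)
            write_growth_association(result, scan_paths[s])
            growth_assoc[s] = sorted(
                growth_associated_reactions(result, config.r_threshold)
            )
            logger.info("stage fluxresponse[%s]: %d growth-associated reactions",
                        s, len(growth_assoc[s]))
        assoc_path.write_text(json.dumps(growth_assoc, indent=1, sort_keys=True) + "\n")

    # --- stage: TF ranking ---------------------------------------------
    gene_sets = []
    for s in a_samples:
        m = read_model(model_paths[s], "json")
        gene_sets.append(genes_of_reactions(m, [r for r in growth_assoc[s]
                                                if r in m.reactions]))
    growth_genes = sorted(frozenset().union(*gene_sets)) if gene_sets else []
    network = load_regulatory_network(
        p["network"], confidence_filter={config.confidence}
    )
    ranking = rank_transcription_factors(network, growth_genes)
    ranking_path = outdir / "tf_ranking.tsv"
    write_tf_ranking(ranking, ranking_path)
    logger.info("stage ranktf: top TF %s",
                ranking.entries[0][0] if ranking.entries else "(none)")

    cache.write(config)
    return PipelineReport(
        config=config,
        de_table=de_table,
        gene_scores=scores,
        extraction=extraction_summary,
        gapfill=gapfill_summary,
        growth_associated=growth_assoc,
        growth_genes=growth_genes,
        tf_ranking=ranking.to_frame(),
        cached_stages=cached,
    )
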