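"""Transcription-factor prioritization.

Given the metabolic genes behind the growth-associated reactions (via
GPR rules) and a regulatory network of TF -> target-gene edges (a
RegNetwork-style table with confidence and evidence labels), rank TFs by
the number of growth-associated target genes they regulate.  This is a
raw target count, not an enrichment statistic; ties are broken
lexicographically by TF id and TFs with no overlap are excluded from the
ranking (available separately for diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class NetworkFormatError(ValueError):
    pass


REQUIRED_COLUMNS = ("TF", "target", "confidence", "evidence")


@dataclass
class RegulatoryNetwork:
    edges: pd.DataFrame               # columns: TF, target, confidence, evidence
    targets: dict[str, frozenset[str]]

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "RegulatoryNetwork":
        edges = edges.drop_duplicates(subset=["TF", "target"]).reset_index(drop=True)
        if (edges["TF"].str.len() == 0).any() or (edges["target"].str.len() == 0).any():
            raise NetworkFormatError("empty TF or target id in network table")
        targets = {
            tf: frozenset(sub["target"])
            for tf, sub in edges.groupby("TF", sort=True)
        }
        return cls(edges=edges, targets=targets)


def load_regulatory_network(path, confidence_filter=None) -> RegulatoryNetwork:
    """Read a TSV with columns TF, target, confidence, evidence (header
    required).  Rows whose confidence is not in ``confidence_filter``
    (when given) are dropped; duplicate (TF, target) pairs collapse to
    one edge."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkFormatError(f"network file missing required columns: {missing}")
    bad = df.index[(df["TF"] == "") | (df["target"] == "")]
    if len(bad):
        raise NetworkFormatError(
            f"malformed network row at line {int(bad[0]) + 2} (empty TF or target)"
        )
    if confidence_filter is not None:
        df = df[df["confidence"].isin(set(confidence_filter))]
    return RegulatoryNetwork.from_edges(df[list(REQUIRED_COLUMNS)])


@dataclass
class TFRanking:
    """TFs ordered by descending count of growth-associated target genes;
    equal counts ordered lexicographically by TF id."""

    entries: list[tuple[str, int, frozenset[str]]]   # (TF, count, overlap genes)

    def top(self, k: int = 10) -> list[tuple[str, int, frozenset[str]]]:
        return self.entries[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (i + 1, tf, n, ",".join(sorted(genes)))
                for i, (tf, n, genes) in enumerate(self.entries)
            ],
            columns=["rank", "TF", "n_growth_genes", "genes"],
        )


def rank_transcription_factors(
    network: RegulatoryNetwork, growth_genes, include_zero: bool = False
) -> TFRanking:
    """Count each TF's targets among ``growth_genes`` and sort descending
    (ties by TF id).  TFs with zero overlap are excluded unless
    ``include_zero`` (diagnostic mode)."""
    growth_genes = frozenset(growth_genes)
    entries = []
    for tf in sorted(network.targets):
        overlap = network.targets[tf] & growth_genes
        if overlap or include_zero:
            entries.append((tf, len(overlap), overlap))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return TFRanking(entries=entries)


def write_tf_ranking(ranking: TFRanking, path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)
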