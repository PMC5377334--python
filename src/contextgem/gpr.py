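"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers combining AND
(enzyme complex: every subunit required) and OR (isozymes: any one
suffices).  The empty rule is a distinguished value meaning the reaction
has no gene association and is treated as gene-independent downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


class GprParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed; carries the
    character position of the offending token."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprRule:
    """Boolean expression tree over gene ids.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``.
    Leaves (``op == "gene"``) carry the gene id in ``gene``; internal
    nodes carry two or more ``children``.
    """

    op: str = "empty"
    gene: str | None = None
    children: tuple["GprRule", ...] = field(default_factory=tuple)

    # -- queries ---------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        """Set of gene ids appearing anywhere in the rule."""
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset({self.gene})
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        """Boolean evaluation against a set of present genes.

        The empty rule evaluates True (gene-independent reaction).
        """
        if self.op == "empty":
            return True
        if self.op == "gene":
            return self.gene in present
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def aggregate(self, score_of, or_reduce=max, and_reduce=min) -> float | None:
        """Fold gene scores through the rule: OR nodes reduced with
        ``or_reduce`` (default max, isozymes add capacity), AND nodes with
        ``and_reduce`` (default min, a complex is limited by its scarcest
        subunit).  Returns None for the empty rule."""
        if self.op == "empty":
            return None
        if self.op == "gene":
            return score_of(self.gene)
        vals = [c.aggregate(score_of, or_reduce, and_reduce) for c in self.children]
        return (and_reduce if self.op == "and" else or_reduce)(vals)

    def to_string(self) -> str:
        """Canonical text form, round-trippable through :func:`parse_gpr`."""
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene
        joiner = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)


EMPTY_GPR = GprRule()

_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|([^\s()]+))")


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:  # only trailing whitespace
            break
        if m.group(1):
            yield ("(", "(", m.start(1))
        elif m.group(2):
            yield (")", ")", m.start(2))
        else:
            word = m.group(3)
            low = word.lower()
            if low in ("and", "or"):
                yield (low, word, m.start(3))
            else:
                yield ("id", word, m.start(3))
        pos = m.end()


def parse_gpr(rule_text: str) -> GprRule:
    """Parse a GPR rule string like ``"(G1 and G2) or G3"``.

    AND binds tighter than OR; both are case-insensitive.  An empty or
    whitespace-only string yields the empty rule.  Malformed input raises
    :class:`GprParseError` with the character position.
    """
    if rule_text is None or not rule_text.strip():
        return EMPTY_GPR
    tokens = list(_tokenize(rule_text))
    result, idx = _parse_or(rule_text, tokens, 0)
    if idx != len(tokens):
        kind, text, pos = tokens[idx]
        raise GprParseError(f"unexpected token {text!r}", pos)
    return result


def _parse_or(src: str, tokens, idx: int) -> tuple[GprRule, int]:
    branches = []
    node, idx = _parse_and(src, tokens, idx)
    branches.append(node)
    while idx < len(tokens) and tokens[idx][0] == "or":
        idx += 1
        node, idx = _parse_and(src, tokens, idx)
        branches.append(node)
    if len(branches) == 1:
        return branches[0], idx
    return GprRule(op="or", children=tuple(branches)), idx


def _parse_and(src: str, tokens, idx: int) -> tuple[GprRule, int]:
    branches = []
    node, idx = _parse_atom(src, tokens, idx)
    branches.append(node)
    while idx < len(tokens) and tokens[idx][0] == "and":
        idx += 1
        node, idx = _parse_atom(src, tokens, idx)
        branches.append(node)
    if len(branches) == 1:
        return branches[0], idx
    return GprRule(op="and", children=tuple(branches)), idx


def _parse_atom(src: str, tokens, idx: int) -> tuple[GprRule, int]:
    if idx >= len(tokens):
        raise GprParseError("dangling operator or empty group", len(src))
    kind, text, pos = tokens[idx]
    if kind == "id":
        return GprRule(op="gene", gene=text), idx + 1
    if kind == "(":
        node, idx = _parse_or(src, tokens, idx + 1)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise GprParseError("unbalanced parentheses: missing ')'", pos)
        return node, idx + 1
    raise GprParseError(f"unexpected token {text!r}", pos)
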