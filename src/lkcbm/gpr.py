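"""Gene–protein–reaction (GPR) Boolean rules.

A GPR is a Boolean tree over gene identifiers in which AND nodes encode
protein complexes (all subunits required) and OR nodes encode isozymes
(any one suffices).  Rules are written and parsed as parenthesised
strings with the keywords ``and`` / ``or``, e.g. ``"(g1 and g2) or g3"``.

The same tree supports two evaluations:

* :meth:`Gpr.evaluate` — Boolean catalysability after deleting a gene set;
* :meth:`Gpr.score` — expression mapping, aggregating gene-level values
  with ``min`` over AND nodes and ``max`` over OR nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

__all__ = ["Gpr", "GprParseError", "parse_gpr", "evaluate_gpr"]


class GprParseError(ValueError):
    """Raised for malformed GPR strings."""


@dataclass(frozen=True)
class Gpr:
    """A node of a GPR Boolean tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the
    gene id in ``gene``; inner nodes carry ≥2 ``children``.
    """

    kind: str
    gene: Optional[str] = None
    children: tuple = ()

    def __post_init__(self):
        if self.kind == "gene":
            if not self.gene:
                raise GprParseError("gene leaf without identifier")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise GprParseError(f"{self.kind!r} node needs >=2 children")
        else:
            raise GprParseError(f"unknown GPR node kind {self.kind!r}")

    # -- queries -----------------------------------------------------------

    @property
    def genes(self) -> frozenset:
        """All gene ids appearing in the tree."""
        if self.kind == "gene":
            return frozenset([self.gene])
        out = frozenset()
        for c in self.children:
            out |= c.genes
        return out

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True iff the reaction is still catalysable with ``deleted`` knocked out."""
        deleted = set(deleted)
        if self.kind == "gene":
            return self.gene not in deleted
        if self.kind == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def score(self, values: Mapping[str, float]) -> Optional[float]:
        """Expression score: min over AND, max over OR.

        AND nodes require data for every child (a complex with an
        unmeasured subunit is unscorable); OR nodes use the available
        children and are unscored only if none has data.  Returns None
        when the node cannot be scored.
        """
        if self.kind == "gene":
            v = values.get(self.gene)
            return None if v is None else float(v)
        child = [c.score(values) for c in self.children]
        if self.kind == "and":
            if any(v is None for v in child):
                return None
            return min(child)
        present = [v for v in child if v is not None]
        return max(present) if present else None

    # -- serialisation -----------------------------------------------------

    def to_string(self, _parent: Optional[str] = None) -> str:
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        inner = sep.join(c.to_string(self.kind) for c in self.children)
        # parenthesise an OR nested under AND (and any nested mixed node)
        if _parent is not None and _parent != self.kind:
            return f"({inner})"
        return inner

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: Optional[str]) -> Optional[Gpr]:
    """Parse a GPR string; empty/None/whitespace gives None (no rule).

    ``and`` binds tighter than ``or``; keywords are case-insensitive
    (``AND``/``OR`` accepted); any other token is a gene id.
    """
    if rule is None:
        return None
    tokens = _TOKEN_RE.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Gpr:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return Gpr("or", children=tuple(terms))

    def parse_and() -> Gpr:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return Gpr("and", children=tuple(factors))

    def parse_atom() -> Gpr:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parenthesis in {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in {rule!r}")
        return Gpr("gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule {rule!r}")
    return node


def evaluate_gpr(expr: Optional[Gpr], deleted: Iterable[str] = ()) -> bool:
    """Module-level convenience: an empty GPR is always catalysed."""
    if expr is None:
        return True
    return expr.evaluate(deleted)
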