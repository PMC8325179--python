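"""Gene-protein-reaction (GPR) boolean expressions.

A GPR states which combinations of gene products enable a reaction, as a
boolean tree of AND/OR nodes over gene-id leaves.  The empty GPR (no gene
association) is represented by ``None`` at call sites and by
:data:`EMPTY` internally; an empty GPR is conventionally satisfied.

Expressions are parsed from the usual COBRA string form, e.g.
``"(g1 and g2) or g3"``.  Operator names are case-insensitive; ``and``
binds tighter than ``or``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FormatError

__all__ = ["GPR", "gene_leaf", "gpr_and", "gpr_or", "parse_gpr"]


@dataclass(frozen=True)
class GPR:
    """A node in a GPR boolean tree.

    ``op`` is ``"gene"`` (leaf, ``gene`` set), ``"and"`` or ``"or"``
    (``children`` set).
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GPR", ...] = field(default_factory=tuple)

    def genes(self) -> frozenset[str]:
        """All gene ids appearing in the tree."""
        if self.op == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, present: Iterable[str]) -> bool:
        """True iff the expression is satisfied when exactly the genes in
        ``present`` are available."""
        present = set(present)
        return self._eval(present)

    def _eval(self, present: set[str]) -> bool:
        if self.op == "gene":
            return self.gene in present
        if self.op == "and":
            return all(c._eval(present) for c in self.children)
        return any(c._eval(present) for c in self.children)

    def rewrite(self, mapping: dict[str, str]) -> Optional["GPR"]:
        """Rewrite gene leaves through ``mapping`` (old id -> new id),
        pruning unmapped branches.

        An unmapped leaf is False: an OR drops it, an AND containing one is
        dropped as a whole.  Returns ``None`` when the entire expression is
        unsatisfiable under the mapping.
        """
        if self.op == "gene":
            new = mapping.get(self.gene)
            return gene_leaf(new) if new is not None else None
        rewritten = [c.rewrite(mapping) for c in self.children]
        if self.op == "and":
            if any(r is None for r in rewritten):
                return None
            return gpr_and(rewritten)
        kept = [r for r in rewritten if r is not None]
        if not kept:
            return None
        return gpr_or(kept)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        if self.op == "and":
            parts = [
                f"({c.to_string()})" if c.op == "or" else c.to_string()
                for c in self.children
            ]
            return " and ".join(parts)
        return " or ".join(c.to_string() for c in self.children)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def gene_leaf(gene: str) -> GPR:
    return GPR("gene", gene=gene)


def _flatten(op: str, children: Iterable[GPR]) -> GPR:
    flat: list[GPR] = []
    for c in children:
        if c.op == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    if len(flat) == 1:
        return flat[0]
    return GPR(op, children=tuple(flat))


def gpr_and(children: Iterable[GPR]) -> GPR:
    return _flatten("and", children)


def gpr_or(children: Iterable[GPR]) -> GPR:
    return _flatten("or", children)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> Optional[GPR]:
    """Parse a GPR string; empty/blank input yields ``None`` (no association).

    Grammar: ``or_expr := and_expr ('or' and_expr)*``;
    ``and_expr := atom ('and' atom)*``; ``atom := gene | '(' or_expr ')'``.
    """
    tokens = _TOKEN.findall(text or "")
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPR:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return gpr_or(terms)

    def parse_and() -> GPR:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return gpr_and(terms)

    def parse_atom() -> GPR:
        tok = peek()
        if tok is None:
            raise FormatError("GPR string ended unexpectedly")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise FormatError(f"unbalanced parenthesis in GPR: {text!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"unexpected token {tok!r} in GPR: {text!r}")
        return gene_leaf(take())

    expr = parse_or()
    if pos != len(tokens):
        raise FormatError(f"trailing tokens in GPR: {text!r}")
    return expr
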