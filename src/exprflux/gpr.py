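"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule links a reaction to the genes whose products catalyse it.
``OR`` joins isozymes (any one suffices), ``AND`` joins subunits of a
protein complex (all are required).  The grammar, with case-insensitive
operators and ``AND`` binding tighter than ``OR``::

    expr   := term ('OR' term)*
    term   := factor ('AND' factor)*
    factor := GENE | '(' expr ')'

Stoichiometric coefficients inside GPR terms are not part of the grammar
and are rejected; gene identifiers may contain letters, digits and the
characters ``_ . : -``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterator, Optional, Tuple, Union

logger = logging.getLogger(__name__)

__all__ = ["GprLeaf", "GprOp", "GprTree", "GprParseError", "parse_gpr", "gpr_to_string", "gpr_genes"]


class GprParseError(ValueError):
    """Raised for malformed GPR strings; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprLeaf:
    gene: str


@dataclass(frozen=True)
class GprOp:
    op: str  # "and" | "or"
    children: Tuple["GprTree", ...]

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("GPR operator node needs >= 2 children")


GprTree = Union[GprLeaf, GprOp]

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize(text: str) -> Iterator[Tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise GprParseError(f"unexpected character {text[pos:].lstrip()[0]!r}", pos)
        tok = m.group(1)
        yield tok, m.start(1)
        pos = m.end()


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprParseError("unexpected end of GPR string", len(self.text))
        self.i += 1
        return tok

    def parse_expr(self) -> GprTree:
        terms = [self.parse_term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_term())
        if len(terms) == 1:
            return terms[0]
        if any(isinstance(t, GprOp) and t.op == "and" for t in terms):
            # legal, but worth flagging: "A or B and C" relies on precedence
            logger.warning(
                "GPR %r mixes AND and OR without full parenthesization; "
                "AND binds tighter than OR",
                self.text,
            )
        return GprOp("or", tuple(terms))

    def parse_term(self) -> GprTree:
        factors = [self.parse_factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.parse_factor())
        if len(factors) == 1:
            return factors[0]
        return GprOp("and", tuple(factors))

    def parse_factor(self) -> GprTree:
        tok = self.peek()
        if tok is None:
            raise GprParseError("dangling operator", len(self.text))
        if tok == "(":
            open_pos = self.pos()
            self.next()
            node = self.parse_expr()
            if self.peek() != ")":
                raise GprParseError("unbalanced parenthesis", open_pos)
            self.next()
            return node
        if tok == ")":
            raise GprParseError("unmatched ')'", self.pos())
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"operator {tok!r} where a gene was expected", self.pos())
        self.next()
        return GprLeaf(tok)


def parse_gpr(text: str) -> Optional[GprTree]:
    """Parse a GPR string into a tree, or return ``None`` for an empty rule.

    Raises :class:`GprParseError` (with position) on malformed input.
    """
    if text is None or not text.strip():
        return None
    parser = _Parser(text)
    tree = parser.parse_expr()
    if parser.peek() is not None:
        raise GprParseError(f"trailing token {parser.peek()!r}", parser.pos())
    return tree


def gpr_to_string(tree: Optional[GprTree]) -> str:
    """Serialize a tree back to a fully parenthesized GPR string."""
    if tree is None:
        return ""
    if isinstance(tree, GprLeaf):
        return tree.gene
    sep = f" {tree.op} "
    parts = []
    for child in tree.children:
        s = gpr_to_string(child)
        if isinstance(child, GprOp):
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_genes(tree: Optional[GprTree]) -> set:
    """All gene identifiers mentioned in a GPR tree."""
    if tree is None:
        return set()
    if isinstance(tree, GprLeaf):
        return {tree.gene}
    out = set()
    for child in tree.children:
        out |= gpr_genes(child)
    return out
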