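"""Boolean gene-protein-reaction (GPR) rules: parsing and expression-conditioned evaluation.

A GPR rule is a boolean expression over gene symbols, e.g. ``"IDO1 or IDO2 or
TDO2"`` or ``"G1 and (G2 or G3)"``.  ``and`` nodes represent enzyme complexes,
``or`` nodes represent isozymes.  Evaluation against a gene -> expression
mapping turns a rule into a reaction activity score:

* leaf        -> the gene's expression value;
* ``and`` node -> minimum over its children (limiting subunit);
* ``or`` node  -> sum over its children (isozymes add capacity; ``or_mode="max"``
  switches to the max convention).

Genes absent from the mapping contribute 0 to an ``or`` node and are skipped
in an ``and`` node; a subtree with no measured gene at all evaluates to NaN so
"no evidence" is distinguishable from "silent".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

__all__ = [
    "Gene",
    "And",
    "Or",
    "GPRExpr",
    "GPRParseError",
    "parse_gpr",
    "reaction_activity_score",
]


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene symbol."""

    symbol: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be a nonempty string")


@dataclass(frozen=True)
class And:
    """Conjunction: all children required (enzyme complex)."""

    children: tuple["GPRExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("'and' node requires >= 2 children")


@dataclass(frozen=True)
class Or:
    """Disjunction: any child suffices (isozymes)."""

    children: tuple["GPRExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("'or' node requires >= 2 children")


GPRExpr = Union[Gene, And, Or]


class GPRParseError(ValueError):
    """Malformed GPR rule; carries the 0-based position of the offending token."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        yield m.group(1), m.start(1)
        pos = m.end()


class _Parser:
    # grammar:  expr := term ('or' term)* ; term := atom ('and' atom)* ;
    #           atom := GENE | '(' expr ')'
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> GPRExpr:
        if not self.tokens:
            raise GPRParseError("empty rule", 0)
        node = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[0]!r}", tok[1])
        return node

    def _expr(self) -> GPRExpr:
        parts = [self._term()]
        while True:
            tok = self._peek()
            if tok is not None and tok[0].lower() == "or":
                self.i += 1
                parts.append(self._term())
            else:
                break
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def _term(self) -> GPRExpr:
        parts = [self._atom()]
        while True:
            tok = self._peek()
            if tok is not None and tok[0].lower() == "and":
                self.i += 1
                parts.append(self._atom())
            else:
                break
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def _atom(self) -> GPRExpr:
        tok, pos = self._next()
        if tok == "(":
            node = self._expr()
            nxt = self._peek()
            if nxt is None or nxt[0] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            self.i += 1
            return node
        if tok == ")":
            raise GPRParseError("unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator {tok!r}", pos)
        return Gene(tok)


def parse_gpr(text: str) -> GPRExpr:
    """Parse a GPR rule string into an expression tree.

    ``and``/``or`` are case-insensitive; ``and`` binds tighter than ``or``;
    parentheses override precedence.  Raises :class:`GPRParseError` with the
    offending position on malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise GPRParseError("empty rule", 0)
    return _Parser(text).parse()


def gpr_to_string(node: GPRExpr) -> str:
    """Canonical string form; ``parse_gpr(gpr_to_string(t)) == t``.

    Every non-leaf child is parenthesized so nested nodes survive the
    round-trip without operator-associativity flattening.
    """
    if isinstance(node, Gene):
        return node.symbol
    parts = [
        gpr_to_string(c) if isinstance(c, Gene) else f"({gpr_to_string(c)})"
        for c in node.children
    ]
    return (" and " if isinstance(node, And) else " or ").join(parts)


def gpr_genes(node: GPRExpr) -> set[str]:
    """All gene symbols appearing in the rule."""
    if isinstance(node, Gene):
        return {node.symbol}
    out: set[str] = set()
    for c in node.children:
        out |= gpr_genes(c)
    return out


def reaction_activity_score(
    gpr: GPRExpr,
    expr: Mapping[str, float],
    or_mode: str = "sum",
) -> float:
    """Evaluate a GPR rule against a gene -> expression (TPM) mapping.

    Returns NaN when no gene of the rule is measured.
    """
    if or_mode not in ("sum", "max"):
        raise ValueError(f"or_mode must be 'sum' or 'max', got {or_mode!r}")
    if isinstance(gpr, Gene):
        val = expr.get(gpr.symbol)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return math.nan
        if val < 0:
            raise ValueError(f"negative expression for {gpr.symbol}: {val}")
        return float(val)
    vals = [reaction_activity_score(c, expr, or_mode) for c in gpr.children]
    measured = [v for v in vals if not math.isnan(v)]
    if not measured:
        return math.nan
    if isinstance(gpr, And):
        return min(measured)
    return sum(measured) if or_mode == "sum" else max(measured)
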