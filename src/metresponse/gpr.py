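"""Gene-protein-reaction (GPR) rule trees.

A GPR rule is a Boolean association between genes and a reaction: AND nodes
model enzyme complexes (every subunit required), OR nodes model isozymes
(any one suffices).  Rules are parsed from the usual string syntax
(``"g1 and (g2 or g3)"``) with AND binding tighter than OR and operators
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = ["GprTree", "GprParseError", "parse_gpr", "serialize_gpr"]


class GprParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprTree:
    """Node of a GPR expression tree.

    ``kind`` is one of ``"GENE"``, ``"AND"``, ``"OR"``.  Gene leaves carry
    the gene identifier in ``gene``; AND/OR nodes carry >= 2 children.
    """

    kind: str
    gene: Optional[str] = None
    children: tuple["GprTree", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind == "GENE":
            if not self.gene:
                raise ValueError("GENE node requires a gene id")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >= 2 children")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> set[str]:
        """All gene ids referenced by the tree."""
        if self.kind == "GENE":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out


_OPERATORS = {"and", "or"}


def _tokenize(rule: str) -> Iterator[tuple[str, str, int]]:
    """Yield (type, text, position); type in {LPAREN, RPAREN, AND, OR, ID}."""
    i, n = 0, len(rule)
    while i < n:
        c = rule[i]
        if c.isspace():
            i += 1
            continue
        if c == "(":
            yield "LPAREN", c, i
            i += 1
        elif c == ")":
            yield "RPAREN", c, i
            i += 1
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            word = rule[i:j]
            low = word.lower()
            if low in _OPERATORS:
                yield low.upper(), word, i
            else:
                yield "ID", word, i
            i = j


class _Parser:
    # grammar: expr := term ('or' term)* ; term := factor ('and' factor)* ;
    # factor := ID | '(' expr ')'

    def __init__(self, rule: str):
        self.tokens = list(_tokenize(rule))
        self.pos = 0
        self.length = len(rule)

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GprTree:
        tree = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return tree

    def _expr(self) -> GprTree:
        terms = [self._term()]
        while self._peek() is not None and self._peek()[0] == "OR":
            self._next()
            terms.append(self._term())
        if len(terms) == 1:
            return terms[0]
        return GprTree("OR", children=tuple(terms))

    def _term(self) -> GprTree:
        factors = [self._factor()]
        while self._peek() is not None and self._peek()[0] == "AND":
            self._next()
            factors.append(self._factor())
        if len(factors) == 1:
            return factors[0]
        return GprTree("AND", children=tuple(factors))

    def _factor(self) -> GprTree:
        tok = self._next()
        if tok is None:
            raise GprParseError("unexpected end of rule", self.length)
        kind, text, pos = tok
        if kind == "ID":
            return GprTree("GENE", gene=text)
        if kind == "LPAREN":
            inner = self._expr()
            closing = self._next()
            if closing is None or closing[0] != "RPAREN":
                raise GprParseError("unbalanced parentheses", pos)
            return inner
        raise GprParseError(f"unexpected token {text!r}", pos)


def parse_gpr(rule: str) -> Optional[GprTree]:
    """Parse a GPR rule string into a :class:`GprTree`.

    Parentheses bind tightest, then AND, then OR; operators are
    case-insensitive; gene identifiers are any non-whitespace tokens that
    are not operators or parentheses.  An empty/whitespace-only rule means
    "no GPR" and returns ``None``.

    Raises
    ------
    GprParseError
        On unbalanced parentheses or dangling operators, with the character
        position of the offending token.
    """
    if rule is None or not rule.strip():
        return None
    return _Parser(rule).parse()


def serialize_gpr(tree: Optional[GprTree]) -> str:
    """Canonical string form of a GPR tree; inverse of :func:`parse_gpr`.

    AND children that are OR nodes are parenthesized (AND binds tighter);
    same-kind nested nodes are parenthesized too so the exact tree shape
    survives a round trip rather than being flattened by the parser.
    """
    if tree is None:
        return ""
    if tree.kind == "GENE":
        return tree.gene
    op = " or " if tree.kind == "OR" else " and "
    parts = []
    for child in tree.children:
        text = serialize_gpr(child)
        needs_parens = child.kind == tree.kind or (
            tree.kind == "AND" and child.kind == "OR"
        )
        if needs_parens:
            text = f"({text})"
        parts.append(text)
    return op.join(parts)
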