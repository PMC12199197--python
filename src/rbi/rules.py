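"""Boolean regulatory and gene-protein-reaction (GPR) rules.

Regulatory rules in empirical gene-regulatory networks and GPR rules in
genome-scale metabolic models are Boolean expressions over named components
(transcription factors or metabolic genes) built from three operators:
``NOT`` (inhibition), ``AND`` (a required complex; series structure) and
``OR`` (alternatives/isozymes; parallel structure).

This module provides an immutable expression tree (:class:`Var`,
:class:`Not`, :class:`And`, :class:`Or`), a parser for the rule strings found
in GRN tables and in COBRA ``gene_reaction_rule`` fields, and small structural
queries used by the reliability engine.

Grammar (precedence NOT > AND > OR, parentheses override)::

    expr   := term ( OR term )*
    term   := factor ( AND factor )*
    factor := NOT factor | '(' expr ')' | IDENT

Keywords are case-insensitive (``and``/``AND``/``And`` are identical, the
lowercase SBML-FBC spelling included); identifiers are case-sensitive and
match ``[A-Za-z0-9_.-]+``. Nested same-operator nodes are flattened
(``A AND (B AND C)`` becomes a single ternary ``AND``): the reliability
recursion is associative for AND/OR so the value is unchanged, and flat trees
are easier to inspect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

__all__ = [
    "BooleanExpr",
    "Var",
    "Not",
    "And",
    "Or",
    "RuleSyntaxError",
    "parse_rule",
    "serialize",
    "variables",
    "is_read_once",
]


@dataclass(frozen=True)
class Var:
    """A named component (TF or gene) appearing in a rule."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")

    def __repr__(self) -> str:
        return f"Var({self.name!r})"


@dataclass(frozen=True)
class Not:
    """Negation (inhibition); exactly one child."""

    child: "BooleanExpr"


@dataclass(frozen=True)
class And:
    """Conjunction over >= 2 children (series structure)."""

    children: tuple["BooleanExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND requires at least 2 children")


@dataclass(frozen=True)
class Or:
    """Disjunction over >= 2 children (parallel structure)."""

    children: tuple["BooleanExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR requires at least 2 children")


BooleanExpr = Union[Var, Not, And, Or]


class RuleSyntaxError(ValueError):
    """Malformed rule string; carries the 0-based position of the offence."""

    def __init__(self, message: str, position: int, text: str) -> None:
        super().__init__(f"{message} at position {position} in rule {text!r}")
        self.position = position
        self.text = text


_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<ident>[A-Za-z0-9_.\-]+))")
_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT"}


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise RuleSyntaxError(
                f"unexpected character {stripped[0]!r}", len(text) - len(stripped), text
            )
        pos = m.end()
        if m.lastgroup == "lpar":
            yield "(", "(", m.start("lpar")
        elif m.lastgroup == "rpar":
            yield ")", ")", m.start("rpar")
        else:
            ident = m.group("ident")
            kind = _KEYWORDS.get(ident.lower(), "IDENT")
            yield kind, ident, m.start("ident")
    yield "EOF", "", len(text)


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    @property
    def current(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, message: str) -> RuleSyntaxError:
        return RuleSyntaxError(message, self.current[2], self.text)

    def parse(self) -> BooleanExpr:
        expr = self.expr()
        kind, value, _ = self.current
        if kind != "EOF":
            raise self.fail(f"unexpected token {value!r}")
        return expr

    def expr(self) -> BooleanExpr:
        parts = [self.term()]
        while self.current[0] == "OR":
            self.advance()
            parts.append(self.term())
        return _or(parts) if len(parts) > 1 else parts[0]

    def term(self) -> BooleanExpr:
        parts = [self.factor()]
        while self.current[0] == "AND":
            self.advance()
            parts.append(self.factor())
        return _and(parts) if len(parts) > 1 else parts[0]

    def factor(self) -> BooleanExpr:
        kind, value, pos = self.current
        if kind == "NOT":
            self.advance()
            return Not(self.factor())
        if kind == "(":
            self.advance()
            inner = self.expr()
            if self.current[0] != ")":
                raise self.fail("unbalanced parentheses: expected ')'")
            self.advance()
            return inner
        if kind == "IDENT":
            self.advance()
            return Var(value)
        if kind == ")":
            raise self.fail("unbalanced parentheses: unexpected ')'")
        if kind in ("AND", "OR"):
            raise self.fail(f"dangling operator {value!r}")
        raise self.fail("empty operand")


def _flatten(parts: list[BooleanExpr], cls: type) -> list[BooleanExpr]:
    out: list[BooleanExpr] = []
    for p in parts:
        if isinstance(p, cls):
            out.extend(p.children)
        else:
            out.append(p)
    return out


def _and(parts: list[BooleanExpr]) -> And:
    return And(tuple(_flatten(parts, And)))


def _or(parts: list[BooleanExpr]) -> Or:
    return Or(tuple(_flatten(parts, Or)))


def parse_rule(text: str) -> BooleanExpr:
    """Parse a Boolean rule string into an expression tree.

    Parameters
    ----------
    text
        Non-empty rule such as ``"(Crp AND (NOT Fnr)) OR Fnr"``. Keywords are
        case-insensitive; identifiers are preserved case-sensitively.

    Raises
    ------
    RuleSyntaxError
        On empty input, unbalanced parentheses, dangling operators or stray
        characters, reporting the offending position.
    """
    if not isinstance(text, str):
        raise TypeError(f"rule must be a string, got {type(text).__name__}")
    if not text.strip():
        raise RuleSyntaxError("empty rule", 0, text)
    return _Parser(text).parse()


def serialize(expr: BooleanExpr) -> str:
    """Render an expression tree back to a parseable rule string.

    ``parse_rule(serialize(e))`` is structurally identical to ``e`` (children
    are parenthesized, so precedence is explicit in the output).
    """
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        return f"NOT {_parenthesized(expr.child)}"
    if isinstance(expr, And):
        return " AND ".join(_parenthesized(c) for c in expr.children)
    if isinstance(expr, Or):
        return " OR ".join(_parenthesized(c) for c in expr.children)
    raise TypeError(f"not a BooleanExpr: {expr!r}")


def _parenthesized(expr: BooleanExpr) -> str:
    if isinstance(expr, Var):
        return expr.name
    return f"({serialize(expr)})"


def variables(expr: BooleanExpr) -> frozenset[str]:
    """Set of distinct component names referenced by the expression."""
    if isinstance(expr, Var):
        return frozenset((expr.name,))
    if isinstance(expr, Not):
        return variables(expr.child)
    if isinstance(expr, (And, Or)):
        out: frozenset[str] = frozenset()
        for c in expr.children:
            out |= variables(c)
        return out
    raise TypeError(f"not a BooleanExpr: {expr!r}")


def _occurrences(expr: BooleanExpr, counts: dict[str, int]) -> None:
    if isinstance(expr, Var):
        counts[expr.name] = counts.get(expr.name, 0) + 1
    elif isinstance(expr, Not):
        _occurrences(expr.child, counts)
    else:
        for c in expr.children:
            _occurrences(c, counts)


def is_read_once(expr: BooleanExpr) -> bool:
    """True iff every variable occurs exactly once in the tree.

    On read-once expressions the compositional series-parallel evaluation is
    the exact Boolean probability; with repeated variables the two diverge
    (see :mod:`rbi.reliability`).
    """
    counts: dict[str, int] = {}
    _occurrences(expr, counts)
    return all(v == 1 for v in counts.values())
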