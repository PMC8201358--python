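"""Boolean rule expressions: AST, parser, renderer, evaluation.

Expressions are the right-hand sides of ``target, factors`` rule lines:
identifiers combined with ``!`` (NOT), ``&`` (AND), ``|`` (OR), parentheses,
and the constants ``0``/``1``.  Precedence is NOT > AND > OR; AND and OR are
left-associative and flattened into n-ary nodes.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "BoolExpr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "ExpressionError",
    "parse_expression",
    "truth_table_equal",
]

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


class ExpressionError(ValueError):
    """Syntax error in a rule expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class BoolExpr:
    """Base class for expression nodes."""

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, assignment: Mapping[str, object]):
        """Evaluate under an assignment of variable names to values.

        Values may be Python bools/ints or numpy boolean arrays; the same
        expression tree serves both the scalar stepper and the bulk bitwise
        transition-map construction.
        """
        raise NotImplementedError

    def render(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class Var(BoolExpr):
    name: str

    def __post_init__(self):
        if not IDENT_RE.fullmatch(self.name):
            raise ValueError(f"invalid identifier: {self.name!r}")

    def variables(self):
        return frozenset([self.name])

    def evaluate(self, assignment):
        try:
            return assignment[self.name]
        except KeyError:
            raise KeyError(f"unknown variable {self.name!r} in expression") from None

    def render(self):
        return self.name


@dataclass(frozen=True)
class Const(BoolExpr):
    value: bool

    def variables(self):
        return frozenset()

    def evaluate(self, assignment):
        return self.value

    def render(self):
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Not(BoolExpr):
    child: BoolExpr

    def variables(self):
        return self.child.variables()

    def evaluate(self, assignment):
        v = self.child.evaluate(assignment)
        if isinstance(v, (bool, int)):
            return not v
        return ~v  # numpy boolean array

    def render(self):
        if isinstance(self.child, (Var, Const, Not)):
            return f"!{self.child.render()}"
        return f"!({self.child.render()})"


def _check_arity(children: tuple) -> tuple:
    children = tuple(children)
    if len(children) < 2:
        raise ValueError("AND/OR nodes require at least 2 children")
    return children


@dataclass(frozen=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self):
        object.__setattr__(self, "children", _check_arity(self.children))

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def evaluate(self, assignment):
        vals = [c.evaluate(assignment) for c in self.children]
        out = vals[0]
        if isinstance(out, (bool, int)):
            return all(bool(v) for v in vals)
        for v in vals[1:]:
            out = out & v
        return out

    def render(self):
        parts = []
        for c in self.children:
            r = c.render()
            if isinstance(c, Or):
                r = f"({r})"
            parts.append(r)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self):
        object.__setattr__(self, "children", _check_arity(self.children))

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def evaluate(self, assignment):
        vals = [c.evaluate(assignment) for c in self.children]
        out = vals[0]
        if isinstance(out, (bool, int)):
            return any(bool(v) for v in vals)
        for v in vals[1:]:
            out = out | v
        return out

    def render(self):
        return " | ".join(c.render() for c in self.children)


# ---------------------------------------------------------------------------
# Parser: hand-written recursive descent.  Grammar:
#   or_expr  := and_expr ('|' and_expr)*
#   and_expr := unary ('&' unary)*
#   unary    := '!' unary | atom
#   atom     := IDENT | '0' | '1' | '(' or_expr ')'

_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            at = len(text) - len(stripped)
            raise ExpressionError(f"unexpected character {stripped[0]!r}", at)
        if m.lastgroup is None:
            break
        yield m.lastgroup, m.group(m.lastgroup), m.start(m.lastgroup)
        pos = m.end()


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.i += 1
        return tok

    def fail(self, message: str):
        tok = self.peek()
        pos = tok[2] if tok is not None else len(self.text)
        raise ExpressionError(message, pos)

    def parse(self) -> BoolExpr:
        if not self.tokens:
            raise ExpressionError("empty expression", 0)
        expr = self.or_expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()[1]!r}")
        return expr

    def or_expr(self) -> BoolExpr:
        children = [self.and_expr()]
        while self.peek() is not None and self.peek()[1] == "|":
            self.next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self) -> BoolExpr:
        children = [self.unary()]
        while self.peek() is not None and self.peek()[1] == "&":
            self.next()
            children.append(self.unary())
        return children[0] if len(children) == 1 else And(tuple(children))

    def unary(self) -> BoolExpr:
        tok = self.peek()
        if tok is None:
            self.fail("missing operand")
        if tok[1] == "!":
            self.next()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> BoolExpr:
        tok = self.next()
        if tok is None:
            raise ExpressionError("missing operand", len(self.text))
        kind, value, pos = tok
        if kind == "ident":
            return Var(value)
        if kind == "const":
            return Const(value == "1")
        if value == "(":
            inner = self.or_expr()
            closing = self.next()
            if closing is None or closing[1] != ")":
                raise ExpressionError("unbalanced parentheses: missing ')'", pos)
            return inner
        raise ExpressionError(f"unexpected token {value!r}", pos)


def parse_expression(text: str) -> BoolExpr:
    """Parse a rule expression into an AST.

    Raises :class:`ExpressionError` with a character position on malformed
    input (unbalanced parentheses, empty operands, stray characters).
    """
    return _Parser(text).parse()


def truth_table_equal(a: BoolExpr, b: BoolExpr, max_vars: int = 10) -> bool:
    """Exhaustively compare two expressions over their combined variable set."""
    names = sorted(a.variables() | b.variables())
    if len(names) > max_vars:
        raise ValueError(f"too many variables for exhaustive comparison: {len(names)}")
    for bits in itertools.product((False, True), repeat=len(names)):
        env = dict(zip(names, bits))
        if bool(a.evaluate(env)) != bool(b.evaluate(env)):
            return False
    return True
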