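"""Exact-rational expression parsing shared by model and arrangement files.

Model files carry rate laws and boundary polynomials as plain strings.  To keep
every downstream symbolic computation exact (Groebner bases, resultants,
factorization over Q), the grammar deliberately excludes floating-point
literals: coefficients must be written as integers or integer ratios such as
``3/2``.  Supported syntax: identifiers, integer literals, ``+ - * /``,
``^`` (or ``**``) with integer exponents, and parentheses.
"""

from __future__ import annotations

import re

import sympy as sp

__all__ = ["ExpressionError", "parse_expression"]


class ExpressionError(ValueError):
    """Raised when an expression string violates the exact-rational grammar."""


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<int>\d+)"
    r"|(?P<pow>\*\*|\^)"
    r"|(?P<op>[+\-*/()]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        if text[pos] == ".":
            raise ExpressionError(
                f"float literal near position {pos}: write rationals as p/q, e.g. 1/2"
            )
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            if stripped[0] == ".":
                raise ExpressionError(
                    f"float literal near position {pos}: write rationals as p/q, e.g. 1/2"
                )
            raise ExpressionError(f"unexpected character {stripped[0]!r} at position {pos}")
        kind = match.lastgroup
        tokens.append((kind, match.group(kind), match.start(kind)))
        pos = match.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser producing sympy expressions over Q[symbols]."""

    def __init__(self, tokens: list[tuple[str, str, int]], symbols: dict[str, sp.Symbol]):
        self.tokens = tokens
        self.symbols = symbols
        self.idx = 0

    def peek(self):
        return self.tokens[self.idx]

    def advance(self):
        tok = self.tokens[self.idx]
        self.idx += 1
        return tok

    def expect(self, kind, value=None):
        tok = self.advance()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise ExpressionError(f"expected {value or kind} at position {tok[2]}, got {tok[1]!r}")
        return tok

    def parse(self) -> sp.Expr:
        expr = self.expr()
        tok = self.peek()
        if tok[0] != "end":
            raise ExpressionError(f"trailing input {tok[1]!r} at position {tok[2]}")
        return expr

    def expr(self) -> sp.Expr:
        node = self.term()
        while self.peek()[:2] in (("op", "+"), ("op", "-")):
            op = self.advance()[1]
            rhs = self.term()
            node = node + rhs if op == "+" else node - rhs
        return node

    def term(self) -> sp.Expr:
        node = self.unary()
        while self.peek()[:2] in (("op", "*"), ("op", "/")):
            op = self.advance()[1]
            rhs = self.unary()
            node = node * rhs if op == "*" else node / rhs
        return node

    def unary(self) -> sp.Expr:
        tok = self.peek()
        if tok[:2] == ("op", "-"):
            self.advance()
            return -self.unary()
        if tok[:2] == ("op", "+"):
            self.advance()
            return self.unary()
        return self.power()

    def power(self) -> sp.Expr:
        base = self.atom()
        if self.peek()[0] == "pow":
            self.advance()
            exponent = self.unary()
            if not isinstance(exponent, sp.Integer):
                raise ExpressionError("exponents must be integer literals")
            return base ** exponent
        return base

    def atom(self) -> sp.Expr:
        kind, value, pos = self.advance()
        if kind == "int":
            return sp.Integer(int(value))
        if kind == "name":
            try:
                return self.symbols[value]
            except KeyError:
                raise ExpressionError(
                    f"undeclared symbol {value!r} at position {pos}"
                ) from None
        if (kind, value) == ("op", "("):
            node = self.expr()
            self.expect("op", ")")
            return node
        raise ExpressionError(f"unexpected token {value!r} at position {pos}")


def parse_expression(text: str, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    """Parse ``text`` into a sympy expression over the declared ``symbols``.

    Raises :class:`ExpressionError` on float literals, undeclared identifiers,
    non-integer exponents, or malformed syntax.
    """
    if not isinstance(text, str):
        raise ExpressionError(f"expected expression string, got {type(text).__name__}")
    expr = _Parser(_tokenize(text), symbols).parse()
    return sp.nsimplify(expr, rational=True) if expr.atoms(sp.Float) else expr
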