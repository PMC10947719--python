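"""Arithmetic and logic expressions over named variables.

Reaction kinetics, differentiation switches, output filters and glyph
coloring are all user-specified as plain text expressions inside the
protocol document, so that arbitrary kinetic models (Monod, Haldane,
double-Monod, thermodynamic variants, ...) can be written without code.

Grammar (infix, standard precedence)::

    logic   :=  and ( '|' and )*
    and     :=  not ( '&' not )*
    not     :=  '!' not | cmp
    cmp     :=  arith ( ('<'|'<='|'='|'=='|'!='|'>='|'>') arith )?
    arith   :=  term ( ('+'|'-') term )*
    term    :=  unary ( ('*'|'/') unary )*
    unary   :=  ('-'|'+') unary | power
    power   :=  atom ( '^' unary )?          # right associative
    atom    :=  NUMBER | NAME | NAME '(' args ')' | '(' logic ')'

``^`` is exponentiation; comparison chaining is not allowed.  Evaluation
is pure: the same bindings always give the same value, an unbound
variable raises :class:`BindingError` (never a silent zero) and division
by zero raises :class:`EvaluationError` carrying the offending
expression and bindings.
"""

from __future__ import annotations

import math
import re
from typing import Callable, Iterable, Mapping

__all__ = [
    "ArithmeticExpression",
    "LogicExpression",
    "ExpressionSyntaxError",
    "BindingError",
    "EvaluationError",
    "parse_arithmetic",
    "parse_logic",
    "evaluate_arithmetic",
    "evaluate_logic",
    "check_dimensions",
    "DimensionError",
]


class ExpressionSyntaxError(ValueError):
    pass


class BindingError(KeyError):
    """A free variable was not bound at evaluation time."""


class EvaluationError(ArithmeticError):
    """Numeric failure during evaluation (division by zero, log of <= 0, ...)."""


_FUNCTIONS: dict[str, Callable[..., float]] = {
    "exp": math.exp,
    "log": math.log,
    "log2": math.log2,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "floor": math.floor,
    "ceil": math.ceil,
}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op><=|>=|==|!=|[-+*/^()<>=,&|!]))"
)

# AST nodes are tuples:
#   ('num', x) ('var', name) ('call', fname, args)
#   ('neg', a) ('+'|'-'|'*'|'/'|'^', a, b)
#   ('cmp', op, a, b) ('&'|'|', a, b) ('not', a)


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise ExpressionSyntaxError(
                f"unexpected character {text[pos:].strip()[0]!r} in {text!r}"
            )
        pos = m.end()
        tokens.append(m.group(m.lastgroup))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionSyntaxError(f"unexpected end of expression in {self.text!r}")
        if expected is not None and tok != expected:
            raise ExpressionSyntaxError(
                f"expected {expected!r}, found {tok!r} in {self.text!r}"
            )
        self.pos += 1
        return tok

    # -- grammar ----------------------------------------------------------
    def logic(self):
        node = self.logic_and()
        while self.peek() == "|":
            self.take()
            node = ("|", node, self.logic_and())
        return node

    def logic_and(self):
        node = self.logic_not()
        while self.peek() == "&":
            self.take()
            node = ("&", node, self.logic_not())
        return node

    def logic_not(self):
        if self.peek() == "!":
            self.take()
            return ("not", self.logic_not())
        return self.comparison()

    def comparison(self):
        node = self.arith()
        tok = self.peek()
        if tok in ("<", "<=", "=", "==", "!=", ">=", ">"):
            self.take()
            op = "=" if tok == "==" else tok
            rhs = self.arith()
            nxt = self.peek()
            if nxt in ("<", "<=", "=", "==", "!=", ">=", ">"):
                raise ExpressionSyntaxError(
                    f"comparison chaining is not allowed in {self.text!r}"
                )
            return ("cmp", op, node, rhs)
        return node

    def arith(self):
        node = self.term()
        while self.peek() in ("+", "-"):
            op = self.take()
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.unary()
        while self.peek() in ("*", "/"):
            op = self.take()
            node = (op, node, self.unary())
        return node

    def unary(self):
        tok = self.peek()
        if tok == "-":
            self.take()
            return ("neg", self.unary())
        if tok == "+":
            self.take()
            return self.unary()
        return self.power()

    def power(self):
        node = self.atom()
        if self.peek() == "^":
            self.take()
            return ("^", node, self.unary())
        return node

    def atom(self):
        tok = self.peek()
        if tok is None:
            raise ExpressionSyntaxError(f"unexpected end of expression in {self.text!r}")
        if tok == "(":
            self.take()
            node = self.logic()
            self.take(")")
            return node
        if re.fullmatch(r"(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?", tok):
            self.take()
            return ("num", float(tok))
        if re.fullmatch(r"[A-Za-z_][A-Za-z_0-9]*", tok):
            self.take()
            if self.peek() == "(":
                self.take()
                args = []
                if self.peek() != ")":
                    args.append(self.logic())
                    while self.peek() == ",":
                        self.take()
                        args.append(self.logic())
                self.take(")")
                if tok not in _FUNCTIONS:
                    raise ExpressionSyntaxError(f"unknown function {tok!r} in {self.text!r}")
                return ("call", tok, tuple(args))
            return ("var", tok)
        raise ExpressionSyntaxError(f"unexpected token {tok!r} in {self.text!r}")


def _free_vars(node, out: set[str]) -> None:
    kind = node[0]
    if kind == "var":
        out.add(node[1])
    elif kind == "num":
        pass
    elif kind == "call":
        for a in node[2]:
            _free_vars(a, out)
    elif kind in ("neg", "not"):
        _free_vars(node[1], out)
    elif kind == "cmp":
        _free_vars(node[2], out)
        _free_vars(node[3], out)
    else:
        _free_vars(node[1], out)
        _free_vars(node[2], out)


def _eval(node, bindings: Mapping[str, float], source: str):
    kind = node[0]
    if kind == "num":
        return node[1]
    if kind == "var":
        try:
            return float(bindings[node[1]])
        except KeyError:
            raise BindingError(
                f"unbound variable {node[1]!r} in {source!r}"
            ) from None
    if kind == "call":
        args = [_eval(a, bindings, source) for a in node[2]]
        try:
            return float(_FUNCTIONS[node[1]](*args))
        except (ValueError, OverflowError, ZeroDivisionError) as exc:
            raise EvaluationError(f"{exc} evaluating {source!r} with {dict(bindings)!r}")
    if kind == "neg":
        return -_eval(node[1], bindings, source)
    if kind == "not":
        return not _eval_bool(node[1], bindings, source)
    if kind == "cmp":
        a = _eval(node[2], bindings, source)
        b = _eval(node[3], bindings, source)
        op = node[1]
        if op == "<":
            return a < b
        if op == "<=":
            return a <= b
        if op == "=":
            return a == b
        if op == "!=":
            return a != b
        if op == ">=":
            return a >= b
        return a > b
    if kind in ("&", "|"):
        a = _eval_bool(node[1], bindings, source)
        if kind == "&":
            return a and _eval_bool(node[2], bindings, source)
        return a or _eval_bool(node[2], bindings, source)
    a = _eval(node[1], bindings, source)
    b = _eval(node[2], bindings, source)
    if kind == "+":
        return a + b
    if kind == "-":
        return a - b
    if kind == "*":
        return a * b
    if kind == "/":
        if b == 0:
            raise EvaluationError(
                f"division by zero evaluating {source!r} with {dict(bindings)!r}"
            )
        return a / b
    if kind == "^":
        try:
            return a**b
        except (OverflowError, ZeroDivisionError, ValueError) as exc:
            raise EvaluationError(f"{exc} evaluating {source!r}")
    raise AssertionError(f"unknown node {node!r}")


def _eval_bool(node, bindings, source) -> bool:
    value = _eval(node, bindings, source)
    if isinstance(value, bool):
        return value
    return bool(value)


def _to_string(node) -> str:
    kind = node[0]
    if kind == "num":
        return repr(node[1])
    if kind == "var":
        return node[1]
    if kind == "call":
        return f"{node[1]}({', '.join(_to_string(a) for a in node[2])})"
    if kind == "neg":
        return f"(-{_to_string(node[1])})"
    if kind == "not":
        return f"(!{_to_string(node[1])})"
    if kind == "cmp":
        return f"({_to_string(node[2])} {node[1]} {_to_string(node[3])})"
    return f"({_to_string(node[1])} {kind} {_to_string(node[2])})"


class ArithmeticExpression:
    """A parsed, immutable arithmetic expression.

    Evaluation is referentially transparent and side-effect free.
    """

    __slots__ = ("source", "_ast", "free_variables")

    def __init__(self, source: str):
        self.source = source
        parser = _Parser(source)
        self._ast = parser.logic()
        if parser.peek() is not None:
            raise ExpressionSyntaxError(
                f"trailing input {parser.peek()!r} in {source!r}"
            )
        names: set[str] = set()
        _free_vars(self._ast, names)
        self.free_variables = frozenset(names)

    def evaluate(self, bindings: Mapping[str, float]) -> float:
        return float(_eval(self._ast, bindings, self.source))

    def __call__(self, **bindings: float) -> float:
        return self.evaluate(bindings)

    def __str__(self) -> str:
        return _to_string(self._ast)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.source!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ArithmeticExpression) and self._ast == other._ast

    def __hash__(self) -> int:
        return hash(repr(self._ast))


class LogicExpression(ArithmeticExpression):
    """A boolean expression; may embed arithmetic sub-expressions."""

    def evaluate(self, bindings: Mapping[str, float]) -> bool:  # type: ignore[override]
        return _eval_bool(self._ast, bindings, self.source)


def parse_arithmetic(text: str) -> ArithmeticExpression:
    return ArithmeticExpression(text)


def parse_logic(text: str) -> LogicExpression:
    return LogicExpression(text)


def evaluate_arithmetic(
    expr: ArithmeticExpression | str, bindings: Mapping[str, float]
) -> float:
    if isinstance(expr, str):
        expr = parse_arithmetic(expr)
    return expr.evaluate(bindings)


def evaluate_logic(expr: LogicExpression | str, bindings: Mapping[str, float]) -> bool:
    if isinstance(expr, str):
        expr = parse_logic(expr)
    return bool(expr.evaluate(bindings))


class DimensionError(ValueError):
    """Dimensionally inconsistent expression for the declared variable units."""


def check_dimensions(
    expr: ArithmeticExpression | str, dimensions: Mapping[str, tuple]
):
    """Infer the dimension of an expression from declared variable dimensions.

    ``dimensions`` maps variable names to (length, mass, time) exponent
    tuples (see :mod:`microsim.units`); undeclared variables are treated
    as dimensionless.  Addition, subtraction and comparison require equal
    dimensions; exponents and transcendental-function arguments must be
    dimensionless.  Returns the expression's dimension tuple.
    """
    from fractions import Fraction

    if isinstance(expr, str):
        expr = parse_arithmetic(expr)
    none = (Fraction(0), Fraction(0), Fraction(0))

    def norm(d):
        return tuple(Fraction(x) for x in d)

    def walk(node):
        kind = node[0]
        if kind == "num":
            return none
        if kind == "var":
            return norm(dimensions.get(node[1], none))
        if kind in ("neg", "not"):
            return walk(node[1])
        if kind == "call":
            args = [walk(a) for a in node[2]]
            if node[1] in ("abs", "min", "max", "floor", "ceil"):
                if len(set(args)) > 1:
                    raise DimensionError(
                        f"{node[1]} over mixed dimensions in {expr.source!r}"
                    )
                return args[0] if args else none
            if node[1] == "sqrt":
                return tuple(x / 2 for x in args[0])
            if any(a != none for a in args):
                raise DimensionError(
                    f"{node[1]} argument must be dimensionless in {expr.source!r}"
                )
            return none
        if kind in ("+", "-", "cmp", "&", "|"):
            operands = node[2:] if kind == "cmp" else node[1:]
            dims = [walk(x) for x in operands]
            if len(set(dims)) > 1:
                raise DimensionError(
                    f"{kind!r} over mixed dimensions in {expr.source!r}"
                )
            return none if kind in ("cmp", "&", "|") else dims[0]
        if kind == "*":
            a, b = walk(node[1]), walk(node[2])
            return tuple(x + y for x, y in zip(a, b))
        if kind == "/":
            a, b = walk(node[1]), walk(node[2])
            return tuple(x - y for x, y in zip(a, b))
        if kind == "^":
            base, power = walk(node[1]), walk(node[2])
            if power != none:
                raise DimensionError(f"exponent has dimensions in {expr.source!r}")
            if base == none:
                return none
            if node[2][0] != "num":
                raise DimensionError(
                    f"dimensioned base needs a constant exponent in {expr.source!r}"
                )
            return tuple(x * Fraction(node[2][1]).limit_denominator(1000) for x in base)
        raise AssertionError(kind)

    return walk(expr._ast)
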