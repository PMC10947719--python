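"""Expression engine: parsing, evaluation, and an independent AST oracle."""

import ast
import itertools
import math
import operator

import numpy as np
import pytest

from microsim.expressions import (
    BindingError,
    EvaluationError,
    ExpressionSyntaxError,
    parse_arithmetic,
    parse_logic,
)


def python_eval_oracle(source: str, bindings: dict) -> float:
    """Independent evaluator built on Python's own parser.

    Translates the expression grammar to Python syntax (^ -> **, = -> ==,
    & -> and, | -> or, ! -> not) and evaluates with Python's ast module.
    """
    txt = source.replace("^", "**")
    txt = txt.replace("!=", "__NE__").replace("==", "__EQ__")
    txt = txt.replace("=", "==").replace("__NE__", "!=").replace("__EQ__", "==")
    txt = txt.replace("&", " and ").replace("|", " or ").replace("!", " not ")
    txt = txt.replace("not =", "!=")  # undo collision from '!='
    tree = ast.parse(txt, mode="eval")
    env = {**bindings, "exp": math.exp, "log": math.log, "sqrt": math.sqrt,
           "min": min, "max": max, "abs": abs}
    return eval(compile(tree, "<oracle>", "eval"), {"__builtins__": {}}, env)


class TestArithmetic:
    def test_monod_half_saturation(self):
        expr = parse_arithmetic("mumax*S/(K+S)")
        assert expr.evaluate({"mumax": 0.8, "S": 3.0, "K": 3.0}) == pytest.approx(0.4)

    def test_monod_zero_substrate(self):
        expr = parse_arithmetic("mumax*S/(K+S)")
        assert expr.evaluate({"mumax": 0.8, "S": 0.0, "K": 3.0}) == 0.0

    def test_precedence_and_power(self):
        expr = parse_arithmetic("2+3*4^2")
        assert expr.evaluate({}) == 50.0
        assert parse_arithmetic("2^3^2").evaluate({}) == 512.0  # right assoc
        assert parse_arithmetic("-2^2").evaluate({}) == -4.0

    def test_functions(self):
        assert parse_arithmetic("exp(0)+log(1)").evaluate({}) == 1.0
        assert parse_arithmetic("min(3, max(1, 2))").evaluate({}) == 2.0
        assert parse_arithmetic("sqrt(abs(-9))").evaluate({}) == 3.0

    def test_random_polynomials_match_oracle(self, rng):
        """Random arithmetic over random bindings matches the Python-ast oracle."""
        names = ["a", "b", "c", "S", "K"]
        ops = ["+", "-", "*", "/"]
        for _ in range(100):
            n_terms = rng.integers(2, 6)
            parts = []
            for t in range(n_terms):
                var = names[rng.integers(0, len(names))]
                coef = round(float(rng.uniform(0.1, 5.0)), 3)
                parts.append(f"({coef}*{var}+{round(float(rng.uniform(0.1, 2)), 3)})")
            source = parts[0]
            for p in parts[1:]:
                source += ops[rng.integers(0, len(ops))] + p
            bindings = {n: float(rng.uniform(0.5, 4.0)) for n in names}
            expected = python_eval_oracle(source, bindings)
            assert parse_arithmetic(source).evaluate(bindings) == pytest.approx(
                expected, rel=1e-12
            )

    def test_unbound_variable_is_error_not_zero(self):
        with pytest.raises(BindingError):
            parse_arithmetic("a + b").evaluate({"a": 1.0})

    def test_division_by_zero_carries_context(self):
        with pytest.raises(EvaluationError) as err:
            parse_arithmetic("1/S").evaluate({"S": 0.0})
        assert "1/S" in str(err.value)

    def test_referential_transparency(self):
        expr = parse_arithmetic("a*exp(-b)")
        b = {"a": 2.0, "b": 0.5}
        assert expr.evaluate(b) == expr.evaluate(b)

    def test_print_parse_roundtrip(self):
        for source in ["mumax*S/(K+S)", "2^3^2", "-(a+b)*c", "min(a, b+1)",
                       "a > 1 & b <= 2"]:
            expr = parse_logic(source)
            again = parse_logic(str(expr))
            assert expr == again

    @pytest.mark.parametrize("bad", ["2 +", "foo(1)", "a b", "1 < 2 < 3", "(a"])
    def test_syntax_errors(self, bad):
        with pytest.raises(ExpressionSyntaxError):
            parse_logic(bad)


class TestLogic:
    def test_boundary_inclusive(self):
        expr = parse_logic("mass >= divisionMass")
        assert expr.evaluate({"mass": 1.0, "divisionMass": 1.0}) is True

    def test_embedded_arithmetic(self):
        expr = parse_logic("S > 0 & inactive = 0")
        assert expr.evaluate({"S": 1.0, "inactive": 0.0}) is True
        assert expr.evaluate({"S": 0.0, "inactive": 0.0}) is False

    def test_truth_tables_exhaustive(self):
        """All four boolean pairs for & and | match Python's and/or."""
        for a, b in itertools.product([0.0, 1.0], repeat=2):
            bindings = {"a": a, "b": b}
            assert parse_logic("a = 1 & b = 1").evaluate(bindings) == (
                bool(a) and bool(b)
            )
            assert parse_logic("a = 1 | b = 1").evaluate(bindings) == (
                bool(a) or bool(b)
            )
            assert parse_logic("!(a = 1)").evaluate(bindings) == (not bool(a))

    def test_comparison_chain_rejected(self):
        with pytest.raises(ExpressionSyntaxError):
            parse_logic("0 < S < 1")


class TestDimensionCheck:
    CONC = (-3, 1, 0)  # mass / length^3
    RATE = (0, 0, -1)  # 1 / time

    def test_monod_is_rate_dimensioned(self):
        from microsim.expressions import check_dimensions

        dims = {"mumax": self.RATE, "S": self.CONC, "K": self.CONC}
        assert tuple(map(int, check_dimensions("mumax*S/(K+S)", dims))) == self.RATE

    def test_adding_concentration_to_rate_rejected(self):
        from microsim.expressions import DimensionError, check_dimensions

        dims = {"mumax": self.RATE, "S": self.CONC}
        with pytest.raises(DimensionError):
            check_dimensions("mumax + S", dims)

    def test_transcendental_needs_dimensionless_argument(self):
        from microsim.expressions import DimensionError, check_dimensions

        with pytest.raises(DimensionError):
            check_dimensions("exp(S)", {"S": self.CONC})
        # ratios are fine
        check_dimensions("exp(S/K)", {"S": self.CONC, "K": self.CONC})


try:
    from hypothesis import given, settings, strategies as st

    _numbers = st.floats(
        min_value=0.01, max_value=100.0, allow_nan=False, allow_infinity=False
    )

    class TestHypothesisProperties:
        @given(a=_numbers, b=_numbers, c=_numbers)
        @settings(max_examples=60, deadline=None, derandomize=True)
        def test_monod_matches_oracle_everywhere(self, a, b, c):
            source = "mumax*S/(K+S) + c0*S"
            bindings = {"mumax": a, "S": b, "K": c, "c0": 0.25}
            assert parse_arithmetic(source).evaluate(bindings) == pytest.approx(
                python_eval_oracle(source, bindings), rel=1e-12
            )

        @given(x=_numbers, y=_numbers)
        @settings(max_examples=60, deadline=None, derandomize=True)
        def test_print_parse_evaluation_invariant(self, x, y):
            expr = parse_arithmetic("(x + 2*y)^2 / (x*y) - min(x, y)")
            again = parse_arithmetic(str(expr))
            bindings = {"x": x, "y": y}
            assert expr.evaluate(bindings) == again.evaluate(bindings)

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
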