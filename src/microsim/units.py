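"""Unit parsing and conversion.

The simulator works internally in a micrometre / femtogram / hour base
system, chosen so that typical cell masses, cell sizes and growth time
scales are numbers of order one, and so that the common laboratory
concentration unit comes out neutral::

    1 g/L  =  1e15 fg / 1e15 um^3  =  1 fg/um^3

Quantities in protocol files are strings such as ``"0.2 /h"``,
``"1.5 g/L"`` or ``"0.01 Pa s"`` and are converted to base units on
load.  Dimensions are tracked as integer exponent triples
``(length, mass, time)`` so that inconsistent unit arithmetic is caught
early.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "Quantity",
    "UnitError",
    "parse_quantity",
    "to_base",
    "convert",
    "DIMENSIONLESS",
]


class UnitError(ValueError):
    """Raised for unknown units or dimensionally inconsistent conversions."""


# dimension exponents: (length, mass, time)
Dim = tuple[Fraction, Fraction, Fraction]

DIMENSIONLESS: Dim = (Fraction(0), Fraction(0), Fraction(0))

_L = (Fraction(1), Fraction(0), Fraction(0))
_M = (Fraction(0), Fraction(1), Fraction(0))
_T = (Fraction(0), Fraction(0), Fraction(1))


def _dim_mul(a: Dim, b: Dim) -> Dim:
    return (a[0] + b[0], a[1] + b[1], a[2] + b[2])


def _dim_pow(a: Dim, n: Fraction) -> Dim:
    return (a[0] * n, a[1] * n, a[2] * n)


_HOUR = 1.0
_SECOND = _HOUR / 3600.0
_METRE = 1.0e6  # um
_GRAM = 1.0e15  # fg
_LITRE = 1.0e15  # um^3 (cubic decimetre)
_NEWTON = (_GRAM * 1e3) * _METRE / _SECOND**2  # fg um / h^2
_PASCAL = _NEWTON / _METRE**2

# unit name -> (factor to base units, dimension)
_UNITS: dict[str, tuple[float, Dim]] = {
    # length
    "m": (_METRE, _L),
    "dm": (_METRE * 1e-1, _L),
    "cm": (_METRE * 1e-2, _L),
    "mm": (_METRE * 1e-3, _L),
    "um": (1.0, _L),
    "µm": (1.0, _L),
    "nm": (1e-3, _L),
    # mass
    "kg": (_GRAM * 1e3, _M),
    "g": (_GRAM, _M),
    "mg": (_GRAM * 1e-3, _M),
    "ug": (_GRAM * 1e-6, _M),
    "µg": (_GRAM * 1e-6, _M),
    "ng": (_GRAM * 1e-9, _M),
    "pg": (_GRAM * 1e-12, _M),
    "fg": (1.0, _M),
    # time
    "s": (_SECOND, _T),
    "sec": (_SECOND, _T),
    "min": (_SECOND * 60, _T),
    "h": (_HOUR, _T),
    "hr": (_HOUR, _T),
    "hour": (_HOUR, _T),
    "d": (24.0, _T),
    "day": (24.0, _T),
    "week": (168.0, _T),
    # volume
    "L": (_LITRE, _dim_pow(_L, Fraction(3))),
    "l": (_LITRE, _dim_pow(_L, Fraction(3))),
    "mL": (_LITRE * 1e-3, _dim_pow(_L, Fraction(3))),
    "ml": (_LITRE * 1e-3, _dim_pow(_L, Fraction(3))),
    "uL": (_LITRE * 1e-6, _dim_pow(_L, Fraction(3))),
    "nL": (_LITRE * 1e-9, _dim_pow(_L, Fraction(3))),
    "fL": (1.0, _dim_pow(_L, Fraction(3))),  # = um^3
    # force / pressure
    "N": (_NEWTON, (_L[0] + 0, Fraction(1), Fraction(-2))),
    "fN": (_NEWTON * 1e-15, (Fraction(1), Fraction(1), Fraction(-2))),
    "pN": (_NEWTON * 1e-12, (Fraction(1), Fraction(1), Fraction(-2))),
    "Pa": (_PASCAL, (Fraction(-1), Fraction(1), Fraction(-2))),
    "kPa": (_PASCAL * 1e3, (Fraction(-1), Fraction(1), Fraction(-2))),
    "MPa": (_PASCAL * 1e6, (Fraction(-1), Fraction(1), Fraction(-2))),
}
# fix N dimension tuple (length exponent 1)
_UNITS["N"] = (_NEWTON, (Fraction(1), Fraction(1), Fraction(-2)))


@dataclass(frozen=True)
class Quantity:
    """A value in base units (um, fg, h) together with its dimension."""

    value: float
    dim: Dim = DIMENSIONLESS

    def __mul__(self, other: "Quantity") -> "Quantity":
        return Quantity(self.value * other.value, _dim_mul(self.dim, other.dim))

    def __truediv__(self, other: "Quantity") -> "Quantity":
        return Quantity(
            self.value / other.value, _dim_mul(self.dim, _dim_pow(other.dim, Fraction(-1)))
        )

    @property
    def is_dimensionless(self) -> bool:
        return self.dim == DIMENSIONLESS


_NUMBER_RE = re.compile(r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*)$")
_TOKEN_RE = re.compile(r"([*/·\s]+)|([A-Za-zµ]+)(?:\^?(-?\d+))?")


def _parse_unit_expr(text: str) -> tuple[float, Dim]:
    """Parse a unit expression like ``g/L``, ``um^3``, ``Pa s`` or ``/h``."""
    factor = 1.0
    dim: Dim = DIMENSIONLESS
    sign = 1  # +1 multiply, -1 divide
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise UnitError(f"cannot parse unit {text!r} at position {pos}")
        pos = m.end()
        if m.group(1) is not None:
            if "/" in m.group(1):
                if m.group(1).count("/") > 1:
                    raise UnitError(f"malformed unit {text!r}")
                sign = -1
            continue
        name = m.group(2)
        if name not in _UNITS:
            raise UnitError(f"unknown unit {name!r} in {text!r}")
        exp = Fraction(int(m.group(3)) if m.group(3) else 1) * sign
        ufac, udim = _UNITS[name]
        factor *= float(ufac) ** float(exp)
        dim = _dim_mul(dim, _dim_pow(udim, exp))
        sign = 1 if sign == 1 else -1  # division binds to the following token only
        if m.group(1) is None and sign == -1:
            sign = 1
    return factor, dim


def parse_quantity(text: str | float | int) -> Quantity:
    """Parse ``"<number> [unit]"`` into a :class:`Quantity` in base units.

    A bare number is dimensionless.  ``"1 g/L"`` -> ``Quantity(1.0, conc)``.
    """
    if isinstance(text, (int, float)):
        return Quantity(float(text))
    m = _NUMBER_RE.match(text)
    if m is None:
        raise UnitError(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    rest = m.group(2).strip()
    if not rest:
        return Quantity(value)
    factor, dim = _parse_unit_expr(rest)
    return Quantity(value * factor, dim)


def to_base(text: str | float | int) -> float:
    """Convenience: parse a quantity string and return the base-unit value."""
    return parse_quantity(text).value


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between unit expressions, checking dimensions."""
    f_fac, f_dim = _parse_unit_expr(from_unit)
    t_fac, t_dim = _parse_unit_expr(to_unit)
    if f_dim != t_dim:
        raise UnitError(f"incompatible dimensions: {from_unit!r} vs {to_unit!r}")
    return value * f_fac / t_fac
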