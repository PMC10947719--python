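"""Reactions: stoichiometry times a rate expression.

The production rate of chemical species i by reaction j is
q_ij = N_ij * r_j, with positive stoichiometry meaning production when
the rate is positive.  Rates are arbitrary arithmetic expressions over
solute concentrations, agent aspects and constants; concentrations are
clamped to zero before evaluation so Monod-type terms stay physical if
a solver produces a small negative transient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

from .expressions import ArithmeticExpression, parse_arithmetic

__all__ = ["Reaction", "production_rate", "clamped_bindings"]

ENVIRONMENT = "environment"
AGENT = "agent"


@dataclass
class Reaction:
    """Named reaction: stoichiometry vector + rate expression.

    ``stoichiometry`` maps chemical species names (solutes or biomass
    kinds) to dimensionless or mass-based coefficients.  Environmental
    rates are volumetric (fg/um^3/h); agent-catalyzed rates are per
    agent (fg/h) and typically proportional to the agent's mass.
    """

    name: str
    stoichiometry: dict[str, float]
    rate: ArithmeticExpression
    catalyst: str = ENVIRONMENT
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.rate, str):
            self.rate = parse_arithmetic(self.rate)
        if self.catalyst not in (ENVIRONMENT, AGENT):
            raise ValueError(f"reaction {self.name!r}: unknown catalyst {self.catalyst!r}")

    def rate_value(self, bindings: Mapping[str, float]) -> float:
        if self.params:
            bindings = {**bindings, **self.params}
        try:
            return self.rate.evaluate(bindings)
        except Exception as exc:
            raise type(exc)(f"reaction {self.name!r}: {exc}") from exc


def clamped_bindings(
    bindings: Mapping[str, float], clamp_names: set[str] | None = None
) -> dict[str, float]:
    """Copy bindings with (selected) negative values clamped to zero."""
    out = dict(bindings)
    names = clamp_names if clamp_names is not None else set(out)
    clamped = [n for n in names if n in out and out[n] < 0.0]
    for n in clamped:
        if out[n] < -1e-9:
            warnings.warn(
                f"negative concentration {n}={out[n]:.3g} clamped to 0", RuntimeWarning
            )
        out[n] = 0.0
    return out


def production_rate(
    reaction: Reaction, bindings: Mapping[str, float]
) -> dict[str, float]:
    """Per-species production rates q_i = N_i * r of a single reaction."""
    r = reaction.rate_value(bindings)
    return {sp: coeff * r for sp, coeff in reaction.stoichiometry.items()}
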