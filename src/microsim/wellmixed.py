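"""Well-mixed compartments: chemostat / batch / retentostat ODEs.

A well-mixed compartment has scalar solute concentrations S_s.  Their
rate of change sums dilution terms over the in/outflows with the
production rates of environmental and agent-catalyzed reactions::

    dS_s/dt = sum_in D_i S_{s,i}  -  sum_out D_i S_s  +  q_s(t)
    q_s(t)  = q_{s,env}(S)  +  q_{s,agents}(S, agents) / V

Dilution rates are D_i = Q_i / V(t); the volume itself obeys
dV/dt = sum Q_in - sum Q_out, so fed-batch and variable-volume reactors
are covered.  Agent masses are integrated jointly with the solutes by
an adaptive stiff solver, closing the mass balance to integrator
tolerance.  An outflow can be flagged to retain agents (retentostat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from .agents import Agent
from .reactions import AGENT, ENVIRONMENT, Reaction, clamped_bindings

__all__ = ["Flow", "WellMixedCompartment", "step_well_mixed"]


@dataclass
class Flow:
    kind: str  # 'in' | 'out'
    rate: float  # volumetric flow Q, um^3/h
    concentrations: dict[str, float] = field(default_factory=dict)
    retain_agents: bool = False

    def __post_init__(self):
        if self.kind not in ("in", "out"):
            raise ValueError(f"flow kind must be 'in' or 'out', got {self.kind!r}")


class SolverError(RuntimeError):
    pass


class WellMixedCompartment:
    """Scalar-concentration compartment with flows, reactions and agents."""

    def __init__(
        self,
        name: str,
        volume: float,
        solutes: dict[str, float],
        flows: list[Flow] | None = None,
        reactions: list[Reaction] | None = None,
        parameters: dict[str, float] | None = None,
    ):
        if volume <= 0:
            raise ValueError("compartment volume must be positive")
        self.name = name
        self.volume = float(volume)
        self.solutes = dict(solutes)
        self.flows = list(flows or [])
        self.reactions = list(reactions or [])
        self.parameters = dict(parameters or {})
        self.agents: list[Agent] = []
        # external mass sources (fg/h), e.g. flux through a connected boundary
        self.external_sources: dict[str, float] = {}
        # cumulative bookkeeping for mass-balance audits (fg per solute)
        self.cum_inflow: dict[str, float] = {s: 0.0 for s in solutes}
        self.cum_outflow: dict[str, float] = {s: 0.0 for s in solutes}
        self.cum_production: dict[str, float] = {s: 0.0 for s in solutes}

    # -- reaction rate assembly -------------------------------------------
    def _env_rates(self, conc: dict[str, float]) -> dict[str, float]:
        q = {s: 0.0 for s in self.solutes}
        bindings = clamped_bindings({**self.parameters, **conc}, set(conc))
        for rxn in self.reactions:
            if rxn.catalyst != ENVIRONMENT:
                continue
            r = rxn.rate_value(bindings)
            for sp, coeff in rxn.stoichiometry.items():
                if sp in q:
                    q[sp] += coeff * r
        return q

    def _agent_rates(
        self, conc: dict[str, float], masses: np.ndarray
    ) -> tuple[dict[str, float], np.ndarray]:
        """Total agent-catalyzed solute rates (fg/h) and per-agent mass rates."""
        q_total = {s: 0.0 for s in self.solutes}
        dm = np.zeros(len(self.agents))
        base = clamped_bindings({**self.parameters, **conc}, set(conc))
        for k, agent in enumerate(self.agents):
            if agent.get("inactive"):
                continue
            bindings = dict(base)
            for name, value in agent.resolved_aspects().items():
                if isinstance(value, (int, float)):
                    bindings.setdefault(name, float(value))
            bindings["mass"] = float(masses[k])
            for rxn in agent.get("reactions", []):
                if rxn.catalyst != AGENT:
                    continue
                r = rxn.rate_value(bindings)
                for sp, coeff in rxn.stoichiometry.items():
                    if sp in q_total:
                        q_total[sp] += coeff * r
                    elif sp == "mass":
                        dm[k] += coeff * r
        return q_total, dm

    # -- time stepping -----------------------------------------------------
    def step(self, dt: float, rtol: float = 1e-10, atol: float = 1e-12) -> None:
        """Advance solutes, volume and agent masses by dt (Eq of motion above)."""
        names = list(self.solutes)
        ns = len(names)
        na = len(self.agents)
        y0 = np.concatenate(
            [
                [self.solutes[s] for s in names],
                [self.volume],
                [a.mass for a in self.agents],
                np.zeros(3 * ns),  # cumulative in / out / production audits
            ]
        )

        def rhs(t, y):
            conc = {s: y[i] for i, s in enumerate(names)}
            vol = max(y[ns], 1e-30)
            masses = y[ns + 1 : ns + 1 + na]
            dy = np.zeros_like(y)
            q_env = self._env_rates(conc)
            q_ag, dm = self._agent_rates(conc, masses)
            dvol = 0.0
            for flow in self.flows:
                d_i = flow.rate / vol
                if flow.kind == "in":
                    dvol += flow.rate
                    for i, s in enumerate(names):
                        sin = flow.concentrations.get(s, 0.0)
                        # d(VS)/dt = Q Sin: rigorous also when V varies;
                        # reduces to D Sin - D S at matched in/outflow
                        dy[i] += d_i * (sin - conc[s])
                        dy[ns + 1 + na + i] += flow.rate * sin  # inflow audit
                else:
                    dvol -= flow.rate
                    for i, s in enumerate(names):
                        # outflow removes volume and mass proportionally:
                        # concentration unchanged, mass audit still charged
                        dy[ns + 1 + na + ns + i] += flow.rate * conc[s]
            for i, s in enumerate(names):
                q = q_env[s] + q_ag[s] / vol + self.external_sources.get(s, 0.0) / vol
                dy[i] += q
                dy[ns + 1 + na + 2 * ns + i] += q * vol
            dy[ns] = dvol
            dy[ns + 1 : ns + 1 + na] = dm
            return dy

        sol = solve_ivp(
            rhs,
            (0.0, dt),
            y0,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise SolverError(
                f"well-mixed ODE integration failed in {self.name!r}: {sol.message}"
            )
        y = sol.y[:, -1]
        for i, s in enumerate(names):
            self.solutes[s] = float(y[i])
        self.volume = float(y[ns])
        for k, agent in enumerate(self.agents):
            new_mass = float(y[ns + 1 + k])
            if new_mass <= 0:
                agent.aspects["inactive"] = 1.0
                continue
            share = new_mass / len(agent.points)
            for p in agent.points:
                p.mass = share
        for i, s in enumerate(names):
            self.cum_inflow[s] += float(y[ns + 1 + na + i])
            self.cum_outflow[s] += float(y[ns + 1 + na + ns + i])
            self.cum_production[s] += float(y[ns + 1 + na + 2 * ns + i])

    def apply_washout(self, dt: float, rng: np.random.Generator) -> list[Agent]:
        """Remove agents with the outflow (unless retained); returns removed."""
        d_out = sum(
            f.rate / self.volume
            for f in self.flows
            if f.kind == "out" and not f.retain_agents
        )
        if d_out <= 0 or not self.agents:
            return []
        p = 1.0 - math.exp(-d_out * dt)
        removed = []
        kept = []
        for agent in self.agents:
            if rng.random() < p:
                removed.append(agent)
            else:
                kept.append(agent)
        self.agents = kept
        return removed

    # -- summaries ---------------------------------------------------------
    def total_agent_mass(self) -> float:
        return sum(a.mass for a in self.agents)


def step_well_mixed(compartment: WellMixedCompartment, dt: float, **kw) -> WellMixedCompartment:
    compartment.step(dt, **kw)
    return compartment
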