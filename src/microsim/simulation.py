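"""The global simulation loop.

A simulation owns a species library, one or more compartments, a root
random stream and a process schedule.  Within one global time step, all
processes due in the step fire in order of (due time, priority, order of
definition); then connected-compartment updates are applied (boundary
concentrations, agent transfers) and the state is saved.  The canonical
process order of a biofilm step is: reactions + diffusion (updates
solute fields and agent masses), agent updates (division,
differentiation, size), mechanical relaxation, then reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .agents import Agent, BACILLUS, COCCUS, LinkRegistry, divide, differentiate, grow, update_geometry
from .mechanics import Plane, RelaxationConfig, RelaxResult, relax, shove
from .observe import density_grid, render_svg, summarize
from .schedule import ProcessSchedule
from .spatial import SpatialCompartment
from .species import SpeciesLibrary
from .wellmixed import WellMixedCompartment

__all__ = ["ProcessSpec", "Simulation", "transfer_agents"]


@dataclass
class ProcessSpec:
    name: str
    compartment: str
    kind: str  # reactions | agent_updates | mechanics | summary | density | render
    time_step: float
    priority: int
    params: dict[str, Any] = field(default_factory=dict)


def transfer_agents(source, sink, agents: list[Agent]) -> None:
    """Move agents between compartments exactly once, conserving mass."""
    ids = {a.id for a in agents}
    moved = [a for a in source.agents if a.id in ids]
    source.agents = [a for a in source.agents if a.id not in ids]
    registry = getattr(source, "registry", None)
    if registry is not None:
        for a in moved:
            registry.drop_agent(a.id)
    sink.agents.extend(moved)


class Simulation:
    def __init__(
        self,
        global_dt: float,
        seed: int = 1,
        end_time: float | None = None,
        name: str = "simulation",
    ):
        if global_dt <= 0:
            raise ValueError("global time step must be positive")
        self.name = name
        self.global_dt = float(global_dt)
        self.end_time = end_time
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.time = 0.0
        self.library = SpeciesLibrary()
        self.compartments: dict[str, Any] = {}
        self.processes: dict[str, ProcessSpec] = {}
        self.schedule = ProcessSchedule()
        self.summaries: dict[str, list[dict]] = {}
        self.renders: dict[str, str] = {}
        self.relaxation = RelaxationConfig()
        self.mechanics_log: list[dict] = []
        self.on_step_end: list[Callable[["Simulation"], None]] = []

    # -- construction ------------------------------------------------------
    def add_compartment(self, compartment) -> None:
        self.compartments[compartment.name] = compartment

    def add_process(
        self,
        name: str,
        compartment: str,
        kind: str,
        time_step: float | None = None,
        priority: int | None = None,
        **params,
    ) -> None:
        step = self.global_dt if time_step is None else float(time_step)
        prio = len(self.processes) if priority is None else priority
        spec = ProcessSpec(name, compartment, kind, step, prio, params)
        self.processes[name] = spec
        self.schedule.add(name, step, prio, first_due=self.time + step)

    # -- process execution -------------------------------------------------
    def _linked_values(self, comp: SpatialCompartment) -> dict[str, dict[str, float]]:
        linked: dict[str, float] = {}
        for (_, _), spec in comp.boundaries.items():
            if spec.kind != "connected" or spec.compartment is None:
                continue
            other = self.compartments[spec.compartment]
            for s in comp.solutes:
                linked[s] = other.solutes.get(s, 0.0)
        return {comp.name: linked}

    def _run_process(self, spec: ProcessSpec) -> None:
        comp = self.compartments[spec.compartment]
        dt = spec.time_step
        if spec.kind == "reactions":
            if isinstance(comp, WellMixedCompartment):
                comp.step(dt, **{k: v for k, v in spec.params.items() if k in ("rtol", "atol")})
            else:
                growth = comp.solve_steady_state(
                    linked_values=self._linked_values(comp),
                    tol=spec.params.get("tol", 1e-9),
                    max_iter=spec.params.get("max_iter", 200),
                    damping=spec.params.get("damping", 1.0),
                    pin_bulk_above=spec.params.get("pin_bulk_above"),
                )
                thickness = getattr(comp, "thickness", 1.0)
                for agent in comp.agents:
                    rate = growth.get(agent.id, 0.0)
                    if rate:
                        grow(agent, dt, rate)
                        update_geometry(agent, thickness, comp.scale_2d)
                # feed connected boundary fluxes back into linked reactors
                for (_, _), bspec in comp.boundaries.items():
                    if bspec.kind == "connected" and bspec.compartment:
                        other = self.compartments[bspec.compartment]
                        for s, flux in comp.boundary_fluxes.items():
                            other.external_sources[s] = -flux
        elif spec.kind == "agent_updates":
            self._agent_updates(comp, dt)
        elif spec.kind == "mechanics":
            self._mechanics(comp, spec)
        elif spec.kind == "summary":
            rows = self.summaries.setdefault(spec.name, [])
            rows.append(summarize(comp, self.time, spec.params.get("filters")))
        elif spec.kind == "density":
            grid = density_grid(
                comp.agents,
                comp.extents,
                spec.params.get("resolution", comp.resolution),
                getattr(comp, "thickness", 1.0),
            )
            self.summaries.setdefault(spec.name, []).append(
                {"time": self.time, "total_mass": grid.total_mass()}
            )
        elif spec.kind == "render":
            self.renders[f"{spec.name}@{self.time:g}"] = render_svg(
                comp, spec.params.get("style")
            )
        else:
            raise ValueError(f"unknown process kind {spec.kind!r}")

    def _agent_updates(self, comp, dt: float) -> None:
        thickness = getattr(comp, "thickness", 1.0)
        scale_2d = getattr(comp, "scale_2d", True)
        registry = getattr(comp, "registry", None)
        # differentiation (morphology switches etc.)
        env_bindings: dict[str, float] = {}
        for agent in list(comp.agents):
            if agent.get("differentiation"):
                if isinstance(comp, SpatialCompartment):
                    vox = comp.voxel_of(agent.center)
                    env_bindings = {
                        n: float(s.field[vox]) for n, s in comp.solutes.items()
                    }
                else:
                    env_bindings = dict(comp.solutes)
                differentiate(agent, env_bindings, self.rng, thickness, scale_2d)
        # division
        newborn: list[Agent] = []
        for agent in list(comp.agents):
            threshold = agent.get("division mass")
            if threshold is None:
                continue
            guard = 0
            while agent.mass >= float(threshold) and guard < 16:
                daughter = divide(agent, self.rng, registry, thickness, scale_2d)
                newborn.append(daughter)
                guard += 1
        comp.agents.extend(newborn)
        # chemostat washout
        if isinstance(comp, WellMixedCompartment):
            comp.apply_washout(dt, self.rng)
        if isinstance(comp, SpatialCompartment):
            comp.wrap_agents()

    def _mechanics(self, comp, spec: ProcessSpec) -> None:
        if not isinstance(comp, SpatialCompartment):
            return
        config = spec.params.get("config", self.relaxation)
        overrides = {}
        if "max_iterations" in spec.params:
            overrides["max_iterations"] = int(spec.params["max_iterations"])
        if "force_tolerance_fn" in spec.params:
            from .forces import FN

            overrides["force_tolerance"] = float(spec.params["force_tolerance_fn"]) * FN
        if "max_displacement" in spec.params:
            overrides["max_displacement"] = float(spec.params["max_displacement"])
        if overrides:
            import dataclasses

            config = dataclasses.replace(config, **overrides)
        method = spec.params.get("method", "fbm")
        if method == "shove":
            result = shove(
                comp.agents,
                comp.domain,
                shoving_factor=spec.params.get("shoving_factor", 1.0),
            )
        else:
            result = relax(
                comp.agents,
                config,
                comp.domain,
                surfaces=comp.surfaces(),
                registry=comp.registry,
            )
        comp.wrap_agents()
        self.mechanics_log.append(
            {
                "time": self.time,
                "compartment": comp.name,
                "iterations": result.iterations,
                "residual_fN": result.residual_force_fn,
                "max_overlap": result.max_overlap,
                "converged": result.converged,
            }
        )

    # -- global stepping ---------------------------------------------------
    def run_global_step(self) -> None:
        t_end = self.time + self.global_dt
        while self.schedule and self.schedule.next_due_time() <= t_end + 1e-12:
            entry = self.schedule.pop_next()
            self.time = min(entry.due, t_end)
            self._run_process(self.processes[entry.process_id])
        self.time = t_end
        for hook in self.on_step_end:
            hook(self)

    def run(self, until: float | None = None) -> None:
        horizon = until if until is not None else self.end_time
        if horizon is None:
            raise ValueError("no end time given")
        while self.time < horizon - 1e-12:
            self.run_global_step()

    # -- convenience -------------------------------------------------------
    def all_agents(self) -> list[Agent]:
        out = []
        for comp in self.compartments.values():
            out.extend(getattr(comp, "agents", []))
        return out

    def total_biomass(self, species: str | None = None) -> float:
        return sum(
            a.mass
            for a in self.all_agents()
            if species is None or a.species == species
        )
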