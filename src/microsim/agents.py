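"""Agents: mass-points, sphere-swept morphologies, growth and division.

An agent is a bag of aspects referencing a shared species definition.
Mechanically it is one mass-point with a spherical volume (coccus) or
two mass-points with a sphere-swept segment (bacillus / filament
segment).  Filaments are chains of bacillus agents connected by link
springs with torsion hinges that straighten the chain (rest angle 180
degrees).

Geometry follows from mass and density: a coccus has the radius of the
equal-mass sphere, a rod keeps its radius constant and grows in length,
with the spherocylinder volume  V = pi r^2 l + 4/3 pi r^3.  In 2D
simulations agents are extruded into a virtual third dimension (default
1 um thin); optional density scaling makes the 2D footprint radius equal
to the radius an equal-mass 3D sphere would have.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

import numpy as np

from .expressions import LogicExpression, parse_logic
from .species import SpeciesLibrary

__all__ = [
    "MassPoint",
    "Agent",
    "LinkRegistry",
    "SpineLink",
    "TorsionHinge",
    "radius_from_volume",
    "volume_from_radius",
    "spherocylinder_volume",
    "spherocylinder_length",
    "scale_density_2d",
    "sphere_circle_packing_factor",
    "grow",
    "divide",
    "differentiate",
    "update_geometry",
]

COCCUS = "coccus"
BACILLUS = "bacillus"

_id_counter = itertools.count(1)


def radius_from_volume(volume: float) -> float:
    """Radius of the sphere of a given volume: r = (3V / 4 pi)^(1/3)."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_from_radius(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


def spherocylinder_volume(radius: float, length: float) -> float:
    """Volume of a sphere-swept segment (capsule) of given radius and core length."""
    return math.pi * radius**2 * length + volume_from_radius(radius)


def spherocylinder_length(volume: float, radius: float) -> float:
    """Core segment length of a capsule with the given volume and radius (>= 0)."""
    return max(0.0, (volume - volume_from_radius(radius)) / (math.pi * radius**2))


def sphere_circle_packing_factor() -> float:
    """Ratio of maximum sphere packing to maximum circle packing density.

    eta_sphere / eta_circle = (pi / sqrt 18) / (pi / sqrt 12) = sqrt(2/3)
    ~ 0.82; multiplying 3D densities by this factor compensates for the
    denser packing of circles in 2D simulations.
    """
    eta_sphere = math.pi / math.sqrt(18.0)
    eta_circle = math.pi / math.sqrt(12.0)
    return eta_sphere / eta_circle


def scale_density_2d(density3d: float, mass: float, thickness: float = 1.0) -> float:
    """Effective density of an extruded 2D agent matching its 3D radius.

    The 2D footprint is a disc of radius r extruded over ``thickness`` h;
    requiring pi r^2 h rho_eff = m with r equal to the radius of an
    equal-mass 3D sphere gives rho_eff.  For h = (4/3) r the effective
    density equals the 3D density.
    """
    r3 = radius_from_volume(mass / density3d)
    return mass / (math.pi * r3**2 * thickness)


@dataclass
class MassPoint:
    """Position + mass; the unit of mechanical integration."""

    position: np.ndarray
    mass: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.mass <= 0:
            raise ValueError("mass-point mass must be positive")


@dataclass
class SpineLink:
    """Linear spring between two points (possibly of different agents)."""

    agent_a: int
    point_a: int
    agent_b: int
    point_b: int
    rest_length: float
    stiffness: float


@dataclass
class TorsionHinge:
    """Angular spring over three chained points; rest angle in radians."""

    refs: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    stiffness: float
    rest_angle: float = math.pi


class LinkRegistry:
    """Inter-agent springs and hinges of one compartment."""

    def __init__(self) -> None:
        self.links: list[SpineLink] = []
        self.hinges: list[TorsionHinge] = []

    def add_link(self, link: SpineLink) -> None:
        self.links.append(link)

    def add_hinge(self, hinge: TorsionHinge) -> None:
        self.hinges.append(hinge)

    def drop_agent(self, agent_id: int) -> None:
        self.links = [
            l for l in self.links if agent_id not in (l.agent_a, l.agent_b)
        ]
        self.hinges = [
            h for h in self.hinges if all(a != agent_id for a, _ in h.refs)
        ]

    def neighbors_of(self, agent_id: int) -> set[int]:
        out = set()
        for l in self.links:
            if l.agent_a == agent_id:
                out.add(l.agent_b)
            elif l.agent_b == agent_id:
                out.add(l.agent_a)
        return out


class Agent:
    """One microbial cell (or inert particle such as an EPS blob)."""

    def __init__(
        self,
        species: str,
        points: list[MassPoint],
        kind: str = COCCUS,
        aspects: dict[str, Any] | None = None,
        library: SpeciesLibrary | None = None,
        agent_id: int | None = None,
        parent_id: int | None = None,
    ):
        self.id = next(_id_counter) if agent_id is None else agent_id
        self.parent_id = parent_id
        self.species = species
        self.points = points
        self.kind = kind
        self.aspects: dict[str, Any] = dict(aspects or {})
        self.library = library
        self.radius = 0.0
        self.rest_length = 0.0

    # -- aspect resolution -------------------------------------------------
    def get(self, name: str, default: Any = None) -> Any:
        if name in self.aspects:
            return self.aspects[name]
        if self.library is not None and self.species in self.library:
            return self.library.resolve(self.species).get(name, default)
        return default

    def resolved_aspects(self) -> dict[str, Any]:
        merged: dict[str, Any] = {}
        if self.library is not None and self.species in self.library:
            merged.update(self.library.resolve(self.species))
        merged.update(self.aspects)
        return merged

    # -- derived state -----------------------------------------------------
    @property
    def mass(self) -> float:
        return sum(p.mass for p in self.points)

    @property
    def dim(self) -> int:
        return len(self.points[0].position)

    @property
    def center(self) -> np.ndarray:
        m = self.mass
        return sum(p.mass * p.position for p in self.points) / m

    @property
    def density(self) -> float:
        return float(self.get("density", 150.0))  # fg/um^3, typical wet biomass

    def body_volume(self) -> float:
        return self.mass / self.density

    def copy_state(self) -> dict:
        return {
            "id": self.id,
            "species": self.species,
            "kind": self.kind,
            "points": [(p.position.copy(), p.mass) for p in self.points],
        }


def _effective_radius(agent: Agent, thickness: float, scale_2d: bool) -> float:
    """Coccus radius from mass, density and (in 2D) the virtual thickness."""
    vol = agent.body_volume()
    if agent.dim == 3 or not math.isfinite(thickness):
        return radius_from_volume(vol)
    if scale_2d:
        return radius_from_volume(vol)  # density rescaled so radii match 3D
    return math.sqrt(vol / (math.pi * thickness))


def update_geometry(agent: Agent, thickness: float = 1.0, scale_2d: bool = True) -> None:
    """Recompute radius / rest length so mass / swept volume = density."""
    if agent.kind == COCCUS:
        agent.radius = _effective_radius(agent, thickness, scale_2d)
        agent.rest_length = 0.0
        return
    # rod: constant radius aspect; grow in length
    radius = float(agent.get("rod radius", 0.4))
    agent.radius = radius
    vol = agent.body_volume()
    if agent.dim == 3:
        agent.rest_length = spherocylinder_length(vol, radius)
    else:
        if scale_2d:
            agent.rest_length = spherocylinder_length(vol, radius)
        else:
            # extruded stadium footprint: m = rho h (2 r l + pi r^2)
            area = vol / thickness
            agent.rest_length = max(0.0, (area - math.pi * radius**2) / (2.0 * radius))


def grow(agent: Agent, dt: float, rate: float) -> Agent:
    """Apply a mass rate (fg/h) over dt; flag instead of going non-positive."""
    dm = rate * dt
    if agent.mass + dm <= 0.0:
        agent.aspects["inactive"] = 1.0
        return agent
    share = dm / len(agent.points)
    for p in agent.points:
        p.mass += share
    return agent


def _division_fraction(cv: float, rng: np.random.Generator) -> float:
    """Daughter mass fraction ~ Normal(0.5, 0.5*cv) truncated at +/- 2 sigma."""
    if cv <= 0:
        return 0.5
    sigma = 0.5 * cv
    while True:
        z = rng.standard_normal()
        if abs(z) <= 2.0:
            return 0.5 + sigma * z


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    while True:
        v = rng.standard_normal(dim)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def divide(
    agent: Agent,
    rng: np.random.Generator,
    registry: LinkRegistry | None = None,
    thickness: float = 1.0,
    scale_2d: bool = True,
) -> Agent:
    """Split the agent; returns the daughter.  Mass is conserved exactly.

    Cocci place daughters in opposite random directions, displaced by the
    daughter radius; rods split along their axis with the two new inner
    points on opposite sides of the mother's center of gravity, leaving
    residual compression for the mechanics solver to resolve.  Filament
    segments stay connected by a spring link and torsion hinges.
    """
    mother_mass = agent.mass
    cv = float(agent.get("division cv", 0.0))
    frac = _division_fraction(cv, rng)
    daughter_mass = frac * mother_mass
    remaining = mother_mass - daughter_mass  # exact complement

    if agent.kind == COCCUS:
        center = agent.center.copy()
        direction = _random_unit(rng, agent.dim)
        daughter = Agent(
            agent.species,
            [MassPoint(center.copy(), daughter_mass)],
            kind=COCCUS,
            aspects={
                k: v for k, v in agent.aspects.items() if not k.startswith("_")
            },
            library=agent.library,
            parent_id=agent.id,
        )
        agent.points[0].mass = remaining
        update_geometry(agent, thickness, scale_2d)
        update_geometry(daughter, thickness, scale_2d)
        agent.points[0].position = center - direction * agent.radius
        daughter.points[0].position = center + direction * daughter.radius
    else:
        a, b = agent.points[0].position.copy(), agent.points[1].position.copy()
        center = agent.center.copy()
        axis = b - a
        norm = float(np.linalg.norm(axis))
        direction = axis / norm if norm > 1e-12 else _random_unit(rng, agent.dim)
        delta = 0.05 * agent.radius
        filament = bool(agent.get("filament", False))
        to_cocci = agent.get("divide into", BACILLUS) == COCCUS and not filament
        if to_cocci:
            # lifecycle: rod pinches into two spherical daughters
            daughter = Agent(
                agent.species,
                [MassPoint(b, daughter_mass)],
                kind=COCCUS,
                aspects={k: v for k, v in agent.aspects.items() if not k.startswith("_")},
                library=agent.library,
                parent_id=agent.id,
            )
            agent.kind = COCCUS
            agent.points = [MassPoint(a, remaining)]
        else:
            daughter = Agent(
                agent.species,
                [
                    MassPoint(center - delta * direction, daughter_mass / 2),
                    MassPoint(a, daughter_mass / 2),
                ],
                kind=BACILLUS,
                aspects={k: v for k, v in agent.aspects.items() if not k.startswith("_")},
                library=agent.library,
                parent_id=agent.id,
            )
            agent.points[0].position = center + delta * direction
            agent.points[0].mass = remaining / 2
            agent.points[1].position = b
            agent.points[1].mass = remaining / 2
            if filament and registry is not None:
                _link_filament(agent, daughter, registry)
        update_geometry(agent, thickness, scale_2d)
        update_geometry(daughter, thickness, scale_2d)
    return daughter


def _link_filament(mother: Agent, daughter: Agent, registry: LinkRegistry) -> None:
    """Connect a new filament segment to its mother, preserving chain topology.

    The daughter takes over the mother's trailing end, so any existing
    link attached to the mother's point 0 is re-attached to the daughter's
    point 1 (the inherited endpoint) before the new junction is added.
    """
    from .forces import FN

    k = float(mother.get("link stiffness", mother.get("spine stiffness", 1e5 * FN)))
    kappa = float(mother.get("torsion stiffness", 1e5 * FN))
    for link in registry.links:
        if link.agent_a == mother.id and link.point_a == 0:
            link.agent_a, link.point_a = daughter.id, 1
        elif link.agent_b == mother.id and link.point_b == 0:
            link.agent_b, link.point_b = daughter.id, 1
    for hinge in registry.hinges:
        hinge_refs = list(hinge.refs)
        for i, (aid, pidx) in enumerate(hinge_refs):
            if aid == mother.id and pidx == 0:
                hinge_refs[i] = (daughter.id, 1)
        hinge.refs = tuple(hinge_refs)
    rest = 0.1 * mother.radius
    registry.add_link(
        SpineLink(mother.id, 0, daughter.id, 0, rest_length=rest, stiffness=k)
    )
    registry.add_hinge(
        TorsionHinge(
            ((mother.id, 1), (mother.id, 0), (daughter.id, 0)),
            stiffness=kappa,
        )
    )
    registry.add_hinge(
        TorsionHinge(
            ((mother.id, 0), (daughter.id, 0), (daughter.id, 1)),
            stiffness=kappa,
        )
    )


def differentiate(
    agent: Agent,
    bindings: Mapping[str, float],
    rng: np.random.Generator,
    thickness: float = 1.0,
    scale_2d: bool = True,
) -> bool:
    """Apply the agent's differentiation rules; returns True when triggered.

    The ``differentiation`` aspect is a list of rules
    ``{"condition": <logic expr>, "module": <module name>}`` evaluated
    against agent aspects plus the supplied environment bindings.  On
    trigger the module's aspects are copied onto the agent atomically;
    a changed ``morphology`` aspect converts the shape in place (mass
    conserved).
    """
    rules = agent.get("differentiation")
    if not rules:
        return False
    full = dict(bindings)
    full["mass"] = agent.mass
    for name, value in agent.resolved_aspects().items():
        if isinstance(value, (int, float)) and " " not in name:
            full.setdefault(name, float(value))
    triggered = False
    for rule in rules:
        cond = rule["condition"]
        if isinstance(cond, str):
            cond = parse_logic(cond)
        if not cond.evaluate(full):
            continue
        module = rule.get("module")
        if module is not None:
            if agent.library is None or module not in agent.library.modules:
                raise KeyError(f"differentiation to undefined module {module!r}")
            agent.aspects.update(agent.library.modules[module])
        agent.aspects.update(rule.get("aspects", {}))
        target = agent.get("morphology", agent.kind)
        if target != agent.kind:
            _switch_morphology(agent, target, rng)
        update_geometry(agent, thickness, scale_2d)
        triggered = True
    return triggered


def _switch_morphology(agent: Agent, target: str, rng: np.random.Generator) -> None:
    if target == BACILLUS and agent.kind == COCCUS:
        center = agent.center.copy()
        mass = agent.mass
        direction = _random_unit(rng, agent.dim)
        eps = 0.1 * max(agent.radius, 1e-3)
        agent.points = [
            MassPoint(center - eps * direction, mass / 2),
            MassPoint(center + eps * direction, mass / 2),
        ]
        agent.kind = BACILLUS
    elif target == COCCUS and agent.kind == BACILLUS:
        center = agent.center.copy()
        mass = agent.mass
        agent.points = [MassPoint(center, mass)]
        agent.kind = COCCUS
    elif target not in (COCCUS, BACILLUS):
        raise ValueError(f"unknown morphology {target!r}")
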