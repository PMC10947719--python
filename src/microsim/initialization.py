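"""Initial states: random and distributed agent spawners.

A random spawner draws i.i.d. uniform positions over an axis-aligned
region; a distributed spawner places agents on a regular, cell-centered
lattice (offset half an interval so patterns are symmetric in the
region).  Two species can be interleaved in alternating, equidistant
positions, the classic initial layout of competition experiments on a
substratum line.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .agents import COCCUS, Agent, MassPoint, update_geometry
from .species import SpeciesLibrary

__all__ = ["SpawnerSpec", "spawn_random", "spawn_distributed", "spawn_alternating"]


@dataclass
class SpawnerSpec:
    species: str
    count: int
    region_lo: tuple[float, ...]
    region_hi: tuple[float, ...]
    interval: float | None = None  # distributed spawner only
    kind: str = "random"


def _make_agent(
    species: str, position: np.ndarray, library: SpeciesLibrary, thickness: float,
    scale_2d: bool = True,
) -> Agent:
    aspects = library.resolve(species) if species in library else {}
    mass = float(aspects.get("initial mass", aspects.get("division mass", 300.0) / 2.0))
    agent = Agent(
        species,
        [MassPoint(np.asarray(position, dtype=float), mass)],
        kind=aspects.get("morphology", COCCUS),
        library=library,
    )
    if agent.kind != COCCUS:
        # split the point into two to realize a rod
        direction = np.zeros(len(position))
        direction[0] = 1.0
        eps = 0.2
        agent.points = [
            MassPoint(np.asarray(position) - eps * direction, mass / 2),
            MassPoint(np.asarray(position) + eps * direction, mass / 2),
        ]
    update_geometry(agent, thickness, scale_2d)
    return agent


def spawn_random(
    spec: SpawnerSpec,
    rng: np.random.Generator,
    library: SpeciesLibrary,
    thickness: float = 1.0,
    scale_2d: bool = True,
) -> list[Agent]:
    lo = np.asarray(spec.region_lo, dtype=float)
    hi = np.asarray(spec.region_hi, dtype=float)
    if np.any(hi < lo):
        raise ValueError("spawner region is inverted")
    agents = []
    for _ in range(spec.count):
        pos = lo + rng.random(len(lo)) * (hi - lo)
        agents.append(_make_agent(spec.species, pos, library, thickness, scale_2d))
    return agents


def _lattice_positions(
    lo: np.ndarray, hi: np.ndarray, count: int, interval: float | None
) -> list[np.ndarray]:
    """Cell-centered lattice filling the region axis by axis."""
    span = hi - lo
    varying = [ax for ax in range(len(lo)) if span[ax] > 1e-12]
    if not varying:
        return [lo.copy() for _ in range(count)]
    if len(varying) == 1:
        ax = varying[0]
        step = interval if interval is not None else span[ax] / count
        if count * step > span[ax] + 1e-9:
            raise ValueError(
                f"distributed spawner overflow: {count} x {step} exceeds region {span[ax]}"
            )
        positions = []
        for i in range(count):
            p = lo.copy()
            p[ax] = lo[ax] + (i + 0.5) * step
            positions.append(p)
        return positions
    # multi-dimensional: nearly square grid over the varying axes
    per_axis = int(math.ceil(count ** (1.0 / len(varying))))
    steps = {ax: span[ax] / per_axis for ax in varying}
    positions = []
    ranges = [range(per_axis) for _ in varying]
    for combo in itertools.product(*ranges):
        if len(positions) >= count:
            break
        p = lo.copy()
        for ax, i in zip(varying, combo):
            p[ax] = lo[ax] + (i + 0.5) * steps[ax]
        positions.append(p)
    return positions


def spawn_distributed(
    spec: SpawnerSpec,
    library: SpeciesLibrary,
    thickness: float = 1.0,
    scale_2d: bool = True,
) -> list[Agent]:
    lo = np.asarray(spec.region_lo, dtype=float)
    hi = np.asarray(spec.region_hi, dtype=float)
    positions = _lattice_positions(lo, hi, spec.count, spec.interval)
    return [
        _make_agent(spec.species, p, library, thickness, scale_2d) for p in positions
    ]


def spawn_alternating(
    species_a: str,
    species_b: str,
    count_total: int,
    region_lo,
    region_hi,
    library: SpeciesLibrary,
    thickness: float = 1.0,
    scale_2d: bool = True,
) -> list[Agent]:
    """ABAB... placement at equidistant positions along the region."""
    lo = np.asarray(region_lo, dtype=float)
    hi = np.asarray(region_hi, dtype=float)
    positions = _lattice_positions(lo, hi, count_total, None)
    agents = []
    for i, p in enumerate(positions):
        name = species_a if i % 2 == 0 else species_b
        agents.append(_make_agent(name, p, library, thickness, scale_2d))
    return agents
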