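"""Observation outputs: summaries, agent lists, density grids, SVG renders.

All observation functions are pure: they never mutate simulation state,
and the same state with the same style always produces byte-identical
output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .agents import BACILLUS, COCCUS, Agent
from .expressions import LogicExpression, parse_logic

__all__ = [
    "summarize",
    "agent_table",
    "density_grid",
    "DensityGrid",
    "RenderStyle",
    "render_svg",
]


def _agent_bindings(agent: Agent) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, value in agent.resolved_aspects().items():
        if isinstance(value, (int, float)) and " " not in name:
            out[name] = float(value)
    out["mass"] = agent.mass
    out["radius"] = agent.radius
    out["segments"] = float(len(agent.points) - (0 if agent.kind == COCCUS else 1))
    return out


def _matches(agent: Agent, flt: LogicExpression, species_names=()) -> bool:
    bindings = _agent_bindings(agent)
    for name in species_names:
        bindings[f"species_{name}"] = 0.0
    bindings[f"species_{agent.species}"] = 1.0
    return bool(flt.evaluate(bindings))


def summarize(
    compartment,
    time: float,
    filters: Mapping[str, str | LogicExpression] | None = None,
) -> dict[str, float]:
    """One summary row: time, solute means, agent counts and masses.

    ``filters`` maps a column suffix to a logic expression over agent
    aspects (``species_<name>`` indicator variables are bound so
    ``"species_RS = 1"`` counts a species).
    """
    row: dict[str, float] = {"time": time}
    if hasattr(compartment, "solutes"):
        for name, sol in compartment.solutes.items():
            value = sol.field.mean() if hasattr(sol, "field") else sol
            row[f"mean_{name}"] = float(value)
    agents = getattr(compartment, "agents", [])
    row["agent_count"] = float(len(agents))
    row["agent_mass"] = float(sum(a.mass for a in agents))
    species_names = {a.species for a in agents}
    for label, expr in (filters or {}).items():
        if isinstance(expr, str):
            expr = parse_logic(expr)
        selected = [a for a in agents if _matches(a, expr, species_names)]
        row[f"count_{label}"] = float(len(selected))
        row[f"mass_{label}"] = float(sum(a.mass for a in selected))
    return row


def agent_table(agents: Iterable[Agent]) -> pd.DataFrame:
    """CSV-ready inventory: id, species, mass, position, morphology, segments."""
    rows = []
    for a in agents:
        center = a.center
        rows.append(
            {
                "id": a.id,
                "species": a.species,
                "mass": a.mass,
                **{f"x{i}": float(center[i]) for i in range(len(center))},
                "morphology": a.kind,
                "segments": len(a.points) - (0 if a.kind == COCCUS else 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DensityGrid:
    """Local biomass density on a regular grid (fg/um^3)."""

    density: np.ndarray
    resolution: float
    voxel_volume: float

    def total_mass(self) -> float:
        return float(self.density.sum()) * self.voxel_volume

    def to_csv(self) -> str:
        if self.density.ndim > 2:
            raise ValueError("CSV export supports 1D/2D grids")
        buf = io.StringIO()
        np.savetxt(buf, np.atleast_2d(self.density), delimiter=",", fmt="%.10g")
        return buf.getvalue()


def density_grid(
    agents: Iterable[Agent],
    extents: tuple[float, ...],
    resolution: float,
    thickness: float = 1.0,
    species_filter: str | None = None,
) -> DensityGrid:
    """Mass histogram over voxels by center of gravity, per unit volume.

    Each voxel receives the full mass of agents whose center of gravity
    lies inside it; division by the voxel volume gives local density, so
    the integral over the grid equals total (filtered) agent mass.
    """
    shape = tuple(int(round(e / resolution)) for e in extents)
    dim = len(extents)
    vol = resolution**dim * (thickness if dim == 2 else 1.0)
    grid = np.zeros(shape)
    for a in agents:
        if species_filter is not None and a.species != species_filter:
            continue
        c = a.center
        idx = tuple(
            min(int(c[ax] // resolution), shape[ax] - 1) for ax in range(dim)
        )
        grid[idx] += a.mass
    return DensityGrid(grid / vol, resolution, vol)


@dataclass
class RenderStyle:
    """Style for vector rendering of a 2D state (or a z-projection of 3D)."""

    width_px: float = 500.0
    species_colors: dict[str, str] = field(default_factory=dict)
    default_color: str = "#3050c8"
    background_solute: str | None = None
    background_max: float | None = None  # concentration rendered black
    # arithmetic expression over agent aspects, scaled to [0, 1], that
    # modulates the glyph brightness (e.g. "mass / divisionMass")
    brightness_expression: str | None = None


def _scale_brightness(color: str, value: float) -> str:
    value = min(max(value, 0.0), 1.0)
    r = int(color[1:3], 16)
    g = int(color[3:5], 16)
    b = int(color[5:7], 16)
    return f"#{int(r * value):02x}{int(g * value):02x}{int(b * value):02x}"


def _gray(value: float, vmax: float) -> str:
    # linear gray-level gradient: zero -> white, vmax -> black
    level = int(round(255 * (1.0 - min(max(value / vmax, 0.0), 1.0))))
    return f"#{level:02x}{level:02x}{level:02x}"


def render_svg(compartment, style: RenderStyle | None = None) -> str:
    """Deterministic SVG 1.1 document of a compartment state.

    Agents are drawn as circles (cocci) or capsules (rods); an optional
    solute field forms a linear gray-level background from zero (white)
    to the stated maximum (black).  3D states are projected
    orthographically along z with painter's-order depth sorting.
    """
    style = style or RenderStyle()
    extents = compartment.extents
    dim = len(extents)
    w, h = extents[0], extents[1] if dim >= 2 else extents[0]
    scale = style.width_px / w
    out = io.StringIO()
    out.write(
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{style.width_px:.0f}" height="{h * scale:.0f}" '
        f'viewBox="0 0 {w:.6g} {h:.6g}">\n'
    )

    def ypix(y: float) -> float:
        return h - y  # flip so the vertical axis points up

    if style.background_solute is not None and hasattr(compartment, "solutes"):
        sol = compartment.solutes[style.background_solute]
        fld = sol.field
        vmax = style.background_max or max(float(fld.max()), 1e-30)
        res = compartment.resolution
        arr = fld if fld.ndim == 2 else fld.reshape(fld.shape[0], -1).max(axis=-1)[:, None]
        nx, ny = arr.shape[0], arr.shape[1]
        for i in range(nx):
            for j in range(ny):
                color = _gray(float(arr[i, j]), vmax)
                out.write(
                    f'<rect x="{i * res:.6g}" y="{ypix((j + 1) * res):.6g}" '
                    f'width="{res:.6g}" height="{res:.6g}" fill="{color}" '
                    'stroke="none"/>\n'
                )
    agents = sorted(
        getattr(compartment, "agents", []),
        key=lambda a: (float(a.center[2]) if dim == 3 else 0.0, a.id),
    )
    brightness = None
    if style.brightness_expression is not None:
        from .expressions import parse_arithmetic

        brightness = parse_arithmetic(style.brightness_expression)
    for a in agents:
        color = style.species_colors.get(a.species, style.default_color)
        if brightness is not None:
            color = _scale_brightness(color, brightness.evaluate(_agent_bindings(a)))
        pts = [p.position for p in a.points]
        if a.kind == COCCUS:
            c = pts[0]
            out.write(
                f'<circle cx="{c[0]:.6g}" cy="{ypix(c[1]) if dim >= 2 else 0:.6g}" '
                f'r="{a.radius:.6g}" fill="{color}"/>\n'
            )
        else:
            (x1, y1), (x2, y2) = (pts[0][:2], pts[1][:2])
            out.write(
                f'<line x1="{x1:.6g}" y1="{ypix(y1):.6g}" x2="{x2:.6g}" '
                f'y2="{ypix(y2):.6g}" stroke="{color}" '
                f'stroke-width="{2 * a.radius:.6g}" stroke-linecap="round"/>\n'
            )
    out.write("</svg>\n")
    return out.getvalue()
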