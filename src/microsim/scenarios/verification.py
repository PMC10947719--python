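"""Solver verification against known analytical solutions.

Each scenario has a closed form; the suite reports the maximum relative
deviation of the simulated steady values from the analytic ones.  The
chemostat scenarios exercise the well-mixed ODE solver (with both
environmental and agent-catalyzed reactions), the 1D profiles exercise
the pseudo-steady-state reaction-diffusion solver, and the relaxation
scenario exercises the force-based mechanics.

Parameter choices (all stated in conventional lab units):

* Non-growing chemostat: inflow substrate 500 mg/L, dilution 0.1/h, a
  fixed population consuming 10 mg/(L h) in total; steady state
  S* = S_in - u/D = 400 mg/L.
* Growing chemostat (Monod): mu_max 0.2/h, K_s 20 mg/L, yield 0.25,
  dilution 0.05/h, inflow 2000 mg/L; steady state
  S* = K_s D / (mu_max - D) = 6.67 mg/L and
  X* = Y (S_in - S*) = 498.33 mg/L.
* Thin cell layer: 10 um of uniformly consuming biomass under a 100 um
  concentration boundary layer, bulk 2 mg/L; flux continuity gives a
  biofilm-surface concentration of 1.8 mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..agents import Agent, MassPoint, update_geometry
from ..geometry import Domain
from ..mechanics import RelaxationConfig, relax
from ..reactions import Reaction
from ..spatial import BoundarySpec, SoluteField, SpatialCompartment
from ..wellmixed import Flow, WellMixedCompartment

__all__ = [
    "chemostat_non_growing",
    "chemostat_growing",
    "diffusion_linear",
    "diffusion_parabolic",
    "thin_cell_layer",
    "thick_cell_layer",
    "relaxation_convergence",
    "run_verification_suite",
]

# 1 mg/L in base units (fg/um^3)
MG_PER_L = 1e-3
OXYGEN_DIFFUSIVITY = 7.2e6  # um^2/h, ~2e-9 m^2/s


@dataclass
class ScenarioResult:
    name: str
    value: float  # simulated
    expected: float  # analytic
    rel_dev: float  # |value - expected| / |expected|
    extras: dict = field(default_factory=dict)


def _rel(value: float, expected: float) -> float:
    return abs(value - expected) / abs(expected)


# ---------------------------------------------------------------------------
# chemostat scenarios
# ---------------------------------------------------------------------------


def chemostat_non_growing(
    t_end: float = 250.0, n_agents: int = 10, return_series: bool = False
):
    """Fixed population consuming substrate at constant rate in a chemostat.

    dS/dt = D (S_in - S) - u with u = 10 mg/(L h): S -> S_in - u/D = 400 mg/L.
    """
    volume = 1e9  # um^3 (1 nL)
    s_in = 500.0 * MG_PER_L
    dilution = 0.1  # 1/h
    uptake_total = 10.0 * MG_PER_L  # fg/um^3/h
    comp = WellMixedCompartment(
        "chemostat",
        volume=volume,
        solutes={"substrate": s_in},
        flows=[
            Flow("in", dilution * volume, {"substrate": s_in}),
            Flow("out", dilution * volume),
        ],
    )
    per_agent = uptake_total * volume / n_agents
    rxn = Reaction(
        "uptake",
        {"substrate": -1.0},
        rate="consumptionRate",
        catalyst="agent",
        params={"consumptionRate": per_agent},
    )
    for _ in range(n_agents):
        agent = Agent(
            "consumer", [MassPoint(np.zeros(1), 150.0)],
            aspects={"reactions": [rxn], "density": 150.0},
        )
        update_geometry(agent)
        comp.agents.append(agent)
    series = []
    if return_series:
        for _ in range(int(t_end)):
            comp.step(1.0)
            series.append(comp.solutes["substrate"] / MG_PER_L)
    else:
        comp.step(t_end)
    expected = s_in - uptake_total / dilution
    value = comp.solutes["substrate"]
    result = ScenarioResult(
        "chemostat_non_growing",
        value / MG_PER_L,
        expected / MG_PER_L,
        _rel(value, expected),
    )
    if return_series:
        result.extras["series"] = series
    return result


def chemostat_growing(t_end: float = 4000.0) -> list[ScenarioResult]:
    """Monod-growing population in a chemostat (deterministic biomass pool).

    S* = Ks D / (mumax - D), X* = Y (S_in - S*).
    """
    volume = 1e9
    mumax, ks, yield_, dilution = 0.2, 20.0 * MG_PER_L, 0.25, 0.05
    s_in = 2000.0 * MG_PER_L
    comp = WellMixedCompartment(
        "chemostat",
        volume=volume,
        solutes={"S": s_in, "X": 5.0 * MG_PER_L},
        flows=[Flow("in", dilution * volume, {"S": s_in}), Flow("out", dilution * volume)],
        reactions=[
            Reaction(
                "growth",
                {"X": 1.0, "S": -1.0 / yield_},
                rate="mumax*S/(Ks+S)*X",
                params={"mumax": mumax, "Ks": ks},
            )
        ],
    )
    comp.step(t_end)
    s_star = ks * dilution / (mumax - dilution)
    x_star = yield_ * (s_in - s_star)
    return [
        ScenarioResult(
            "chemostat_growing_substrate",
            comp.solutes["S"] / MG_PER_L,
            s_star / MG_PER_L,
            _rel(comp.solutes["S"], s_star),
        ),
        ScenarioResult(
            "chemostat_growing_biomass",
            comp.solutes["X"] / MG_PER_L,
            x_star / MG_PER_L,
            _rel(comp.solutes["X"], x_star),
        ),
    ]


def chemostat_washout(t_end: float = 700.0) -> ScenarioResult:
    """Dilution above the maximal growth rate at inflow substrate: washout."""
    volume = 1e9
    mumax, ks, yield_ = 0.2, 20.0 * MG_PER_L, 0.25
    s_in = 2000.0 * MG_PER_L
    # critical dilution = mumax * S_in / (Ks + S_in); exceed it by 10%
    d_crit = mumax * s_in / (ks + s_in)
    dilution = 1.1 * d_crit
    comp = WellMixedCompartment(
        "chemostat",
        volume=volume,
        solutes={"S": s_in, "X": 50.0 * MG_PER_L},
        flows=[Flow("in", dilution * volume, {"S": s_in}), Flow("out", dilution * volume)],
        reactions=[
            Reaction(
                "growth",
                {"X": 1.0, "S": -1.0 / yield_},
                rate="mumax*S/(Ks+S)*X",
                params={"mumax": mumax, "Ks": ks},
            )
        ],
    )
    comp.step(t_end)
    return ScenarioResult(
        "chemostat_washout",
        comp.solutes["X"] / MG_PER_L,
        0.0,
        abs(comp.solutes["X"] / MG_PER_L),
    )


# ---------------------------------------------------------------------------
# 1D diffusion-reaction profiles
# ---------------------------------------------------------------------------


def diffusion_linear(n_cells: int = 100) -> ScenarioResult:
    """No reaction, Dirichlet 0 / 1 at the two ends: linear profile."""
    height = 100.0
    h = height / n_cells
    comp = SpatialCompartment(
        "column",
        (height,),
        h,
        boundaries={
            (0, 0): BoundarySpec("dirichlet", {"tracer": 0.0}),
            (0, 1): BoundarySpec("dirichlet", {"tracer": 1.0}),
        },
    )
    comp.add_solute(SoluteField("tracer", OXYGEN_DIFFUSIVITY), initial=0.0)
    comp.solve_steady_state()
    x = (np.arange(n_cells) + 0.5) * h
    exact = x / height
    value = comp.solutes["tracer"].field
    dev = float(np.max(np.abs(value - exact)) / np.max(np.abs(exact)))
    return ScenarioResult("diffusion_linear", float(value[-1]), float(exact[-1]), dev)


def diffusion_parabolic(n_cells: int = 200) -> ScenarioResult:
    """Uniform zero-order consumption, fixed top, no-flux bottom.

    S(x) = S_top - q0/(2 w) (L^2 - x^2), exact closed form.
    """
    height = 100.0
    h = height / n_cells
    s_top = 2.0 * MG_PER_L
    q0 = 1.44  # fg/um^3/h: drop q0 L^2/(2 w) = 1 mg/L, profile stays positive
    omega = OXYGEN_DIFFUSIVITY
    comp = SpatialCompartment(
        "column",
        (height,),
        h,
        boundaries={
            (0, 0): BoundarySpec("noflux"),
            (0, 1): BoundarySpec("dirichlet", {"oxygen": s_top}),
        },
    )
    comp.add_solute(SoluteField("oxygen", omega), initial=s_top)
    comp.add_reaction(
        Reaction("consumption", {"oxygen": -1.0}, rate="q0", params={"q0": q0})
    )
    comp.solve_steady_state()
    x = (np.arange(n_cells) + 0.5) * h
    exact = s_top - q0 / (2 * omega) * (height**2 - x**2)
    value = comp.solutes["oxygen"].field
    dev = float(np.max(np.abs(value - exact)) / np.max(np.abs(exact)))
    return ScenarioResult(
        "diffusion_parabolic", float(value[0] / MG_PER_L), float(exact[0] / MG_PER_L), dev
    )


def _cell_layer_column(
    layer_height: float,
    total_height: float,
    n_cells: int,
    uptake_per_volume: float,
    bulk: float,
    monod_k: float | None = None,
):
    """1D column with a uniformly consuming cell layer at the bottom."""
    h = total_height / n_cells
    comp = SpatialCompartment(
        "biofilm-column",
        (total_height,),
        h,
        boundaries={
            (0, 0): BoundarySpec("noflux"),
            (0, 1): BoundarySpec("dirichlet", {"oxygen": bulk}),
        },
    )
    comp.add_solute(SoluteField("oxygen", OXYGEN_DIFFUSIVITY), initial=bulk)
    n_layer = int(round(layer_height / h))
    rate_per_agent = uptake_per_volume * comp.voxel_volume
    if monod_k is None:
        rxn = Reaction(
            "respiration",
            {"oxygen": -1.0},
            rate="uptakeRate",
            catalyst="agent",
            params={"uptakeRate": rate_per_agent},
        )
    else:
        rxn = Reaction(
            "respiration",
            {"oxygen": -1.0},
            rate="uptakeRate*oxygen/(Km+oxygen)",
            catalyst="agent",
            params={"uptakeRate": rate_per_agent, "Km": monod_k},
        )
    for i in range(n_layer):
        agent = Agent(
            "cells",
            [MassPoint(np.array([(i + 0.5) * h]), 150.0)],
            aspects={"reactions": [rxn], "density": 150.0},
        )
        update_geometry(agent)
        comp.agents.append(agent)
    return comp, h


def thin_cell_layer(n_cells: int = 220) -> ScenarioResult:
    """Thin consuming layer: surface concentration from flux continuity.

    A 10 um cell layer consuming q0 = 1.44 fg/(um^3 h) under a 100 um
    concentration boundary layer with 2 mg/L bulk oxygen:
    S_surface = S_bulk - q0 Lf (H - Lf) / w = 1.8 mg/L.
    """
    layer = 10.0
    total = 110.0
    bulk = 2.0 * MG_PER_L
    q0 = 1.44  # fg/um^3/h
    comp, h = _cell_layer_column(layer, total, n_cells, q0, bulk)
    comp.solve_steady_state()
    fld = comp.solutes["oxygen"].field
    # interpolate the field at the biofilm surface (a voxel face)
    i_face = int(round(layer / h))
    surface = 0.5 * (fld[i_face - 1] + fld[i_face])
    expected = bulk - q0 * layer * (total - layer) / OXYGEN_DIFFUSIVITY
    return ScenarioResult(
        "thin_cell_layer",
        float(surface / MG_PER_L),
        float(expected / MG_PER_L),
        _rel(surface, expected),
    )


def thick_cell_layer(n_cells: int = 220) -> ScenarioResult:
    """Thick consuming layer: oxygen depleted inside, linear in the boundary layer.

    No closed form at the printed precision (the depletion front position
    is free); the reported deviation is the maximum departure from
    linearity of the profile in the concentration boundary layer.
    """
    layer = 40.0
    total = 110.0
    bulk = 2.0 * MG_PER_L
    q0 = 14.4  # fg/um^3/h, 10x the thin-layer biomass: depletion inside
    comp, h = _cell_layer_column(layer, total, n_cells, q0, bulk, monod_k=0.02 * MG_PER_L)
    comp.solve_steady_state(damping=1.0, max_iter=400, tol=1e-8)
    fld = comp.solutes["oxygen"].field
    i_face = int(round(layer / h))
    x = (np.arange(n_cells) + 0.5) * h
    bl = slice(i_face + 1, n_cells)
    coeffs = np.polyfit(x[bl], fld[bl], 1)
    fit = np.polyval(coeffs, x[bl])
    nonlinearity = float(np.max(np.abs(fld[bl] - fit)) / bulk)
    result = ScenarioResult(
        "thick_cell_layer", float(fld[i_face] / MG_PER_L), float("nan"), nonlinearity
    )
    result.extras["profile"] = fld / MG_PER_L
    result.extras["depleted_min"] = float(fld.min() / MG_PER_L)
    return result


# ---------------------------------------------------------------------------
# mechanical relaxation convergence
# ---------------------------------------------------------------------------


def relaxation_convergence(
    n_agents: int = 16, seed: int = 7, chunks: int = 80, iters_per_chunk: int = 5
) -> dict:
    """Over-compressed random cluster: residual force decays towards zero."""
    rng = np.random.default_rng(seed)
    domain = Domain((20.0, 20.0), (False, False))
    agents = []
    for _ in range(n_agents):
        a = Agent(
            "blob",
            [MassPoint(np.array([8.0, 8.0]) + 4.0 * rng.random(2), 300.0)],
            aspects={"density": 150.0},
        )
        update_geometry(a)
        agents.append(a)
    config = RelaxationConfig(max_iterations=iters_per_chunk)
    residuals = []
    for _ in range(chunks):
        result = relax(agents, config, domain)
        residuals.append(result.residual_force)
        if result.converged:
            break
    from ..forces import FN

    return {
        "residual_series_fn": [r / FN for r in residuals],
        "converged": result.converged,
        "final_max_overlap": result.max_overlap,
    }


# ---------------------------------------------------------------------------
# the suite
# ---------------------------------------------------------------------------


def run_verification_suite(include_mechanics: bool = False) -> dict:
    """Run all closed-form verification scenarios.

    Returns a report with per-scenario simulated / analytic values and
    the maximum relative deviation in percent across scenarios.
    """
    results: list[ScenarioResult] = []
    results.append(chemostat_non_growing())
    results.extend(chemostat_growing())
    results.append(diffusion_linear())
    results.append(diffusion_parabolic())
    results.append(thin_cell_layer())
    report = {
        "scenarios": {
            r.name: {
                "value": r.value,
                "expected": r.expected,
                "rel_dev_percent": 100.0 * r.rel_dev,
            }
            for r in results
        },
        "max_rel_dev_percent": 100.0 * max(r.rel_dev for r in results),
    }
    if include_mechanics:
        report["relaxation"] = relaxation_convergence()
    return report
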