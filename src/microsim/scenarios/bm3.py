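"""Configurable multi-species nitrifying-biofilm skeleton.

Heterotrophs (consuming organic substrate S_S and oxygen) and nitrifiers
(consuming ammonium S_N and oxygen) grow in a biofilm compartment whose
top face exchanges solutes diffusively with a connected, continuously
fed bulk reactor.  Both guilds decay by endogenous respiration; agents
that drop below 20% of their division mass become inactive.  Kinetic
and stoichiometric parameters are deliberately *not* defaulted: the
scenario is a skeleton that the user parameterizes, and a missing
parameter raises an error listing every unset value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..protocol import loads
from ..simulation import Simulation

__all__ = ["REQUIRED_BM3_PARAMETERS", "Bm3Report", "build_bm3_protocol", "run_bm3_skeleton"]

REQUIRED_BM3_PARAMETERS = [
    "mumax_H",  # heterotroph maximum growth rate, 1/h
    "Ks_S",  # organic substrate half-saturation, fg/um^3
    "Ko_H",  # heterotroph oxygen half-saturation, fg/um^3
    "Y_H",  # heterotroph yield, fg biomass / fg substrate
    "b_H",  # heterotroph decay rate, 1/h
    "mumax_N",  # nitrifier maximum growth rate, 1/h
    "Ks_N",  # ammonium half-saturation, fg/um^3
    "Ko_N",  # nitrifier oxygen half-saturation, fg/um^3
    "Y_N",  # nitrifier yield, fg biomass / fg ammonium
    "b_N",  # nitrifier decay rate, 1/h
    "S_S_in",  # inflow organic substrate, fg/um^3
    "S_N_in",  # inflow ammonium, fg/um^3
    "S_O2_bulk",  # bulk oxygen (held by aeration), fg/um^3
    "dilution",  # bulk dilution rate, 1/h
    "bulk_volume",  # bulk volume, um^3
]


class MissingParametersError(ValueError):
    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"unset scenario parameters: {', '.join(missing)}")


@dataclass
class Bm3Report:
    bulk_series: list[dict]
    final_bulk: dict[str, float]
    inactive_count: int
    total_biomass: float
    mass_balance_residual: dict[str, float]


def build_bm3_protocol(
    params: dict[str, float],
    seed: int = 1,
    width: float = 40.0,
    height: float = 40.0,
    resolution: float = 2.0,
    dt: float = 1.0,
    t_end: float = 48.0,
    n_each: int = 8,
    mechanics: str = "fbm",
) -> str:
    missing = [k for k in REQUIRED_BM3_PARAMETERS if k not in params]
    if missing:
        raise MissingParametersError(missing)
    p = params
    division_mass = 300.0
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<simulation name="bm3-skeleton">
  <settings timeStep="{dt} h" endTime="{t_end} h" seed="{seed}"/>
  <speciesLib>
    <module name="coccoid">
      <aspect name="density" value="150 fg/um^3"/>
      <aspect name="division mass" value="{division_mass} fg"/>
      <aspect name="division cv" value="0.05"/>
      <aspect name="initial mass" value="{division_mass / 2} fg"/>
      <aspect name="inactivationMass" value="{0.2 * division_mass} fg"/>
      <aspect name="inactive" value="0"/>
    </module>
    <module name="dormant">
      <aspect name="inactive" value="1"/>
    </module>
    <species name="heterotroph">
      <moduleRef name="coccoid"/>
      <aspect name="differentiation">
        <rule condition="mass &lt; inactivationMass" module="dormant"/>
      </aspect>
      <aspect name="reactions">
        <reaction name="growthH" catalyst="agent"
            rate="mumaxH*SS/(KsS+SS)*SO2/(KoH+SO2)*mass">
          <param name="mumaxH" value="{p['mumax_H']}"/>
          <param name="KsS" value="{p['Ks_S']}"/>
          <param name="KoH" value="{p['Ko_H']}"/>
          <stoich species="mass" coefficient="1"/>
          <stoich species="SS" coefficient="{-1.0 / p['Y_H']}"/>
          <stoich species="SO2" coefficient="{-(1.0 - p['Y_H']) / p['Y_H']}"/>
        </reaction>
        <reaction name="decayH" catalyst="agent" rate="bH*mass">
          <param name="bH" value="{p['b_H']}"/>
          <stoich species="mass" coefficient="-1"/>
          <stoich species="SO2" coefficient="-1"/>
        </reaction>
      </aspect>
    </species>
    <species name="nitrifier">
      <moduleRef name="coccoid"/>
      <aspect name="differentiation">
        <rule condition="mass &lt; inactivationMass" module="dormant"/>
      </aspect>
      <aspect name="reactions">
        <reaction name="growthN" catalyst="agent"
            rate="mumaxN*SN/(KsN+SN)*SO2/(KoN+SO2)*mass">
          <param name="mumaxN" value="{p['mumax_N']}"/>
          <param name="KsN" value="{p['Ks_N']}"/>
          <param name="KoN" value="{p['Ko_N']}"/>
          <stoich species="mass" coefficient="1"/>
          <stoich species="SN" coefficient="{-1.0 / p['Y_N']}"/>
          <stoich species="SO2" coefficient="{-4.57 / p['Y_N']}"/>
        </reaction>
        <reaction name="decayN" catalyst="agent" rate="bN*mass">
          <param name="bN" value="{p['b_N']}"/>
          <stoich species="mass" coefficient="-1"/>
          <stoich species="SO2" coefficient="-1"/>
        </reaction>
      </aspect>
    </species>
  </speciesLib>
  <compartment name="bulk" type="wellMixed" volume="{p['bulk_volume']} um^3">
    <solute name="SS" initial="{p['S_S_in']} fg/um^3"/>
    <solute name="SN" initial="{p['S_N_in']} fg/um^3"/>
    <solute name="SO2" initial="{p['S_O2_bulk']} fg/um^3"/>
    <flow kind="in" rate="{p['dilution'] * p['bulk_volume']} um^3/h">
      <concentration solute="SS" value="{p['S_S_in']} fg/um^3"/>
      <concentration solute="SN" value="{p['S_N_in']} fg/um^3"/>
      <concentration solute="SO2" value="{p['S_O2_bulk']} fg/um^3"/>
    </flow>
    <flow kind="out" rate="{p['dilution'] * p['bulk_volume']} um^3/h"/>
    <process name="bulkOde" type="reactions" timeStep="{dt} h" priority="0"/>
  </compartment>
  <compartment name="biofilm" type="spatial" resolution="{resolution} um">
    <shape extents="{width} um, {height} um"/>
    <boundary axis="x" side="min" type="periodic"/>
    <boundary axis="x" side="max" type="periodic"/>
    <boundary axis="y" side="min" type="noflux"/>
    <boundary axis="y" side="max" type="connected" compartment="bulk"/>
    <solute name="SS" initial="{p['S_S_in']} fg/um^3" diffusivity="2.1e6 um^2/h"/>
    <solute name="SN" initial="{p['S_N_in']} fg/um^3" diffusivity="6.1e6 um^2/h"/>
    <solute name="SO2" initial="{p['S_O2_bulk']} fg/um^3" diffusivity="7.2e6 um^2/h"/>
    <process name="reactions" type="reactions" timeStep="{dt} h" priority="1"/>
    <process name="agentUpdates" type="agent_updates" timeStep="{dt} h" priority="2"/>
    <process name="mechanics" type="mechanics" timeStep="{dt} h" priority="3">
      <param name="method" value="{'shove' if mechanics == 'shove' else 'fbm'}"/>
    </process>
    <spawn type="random" species="heterotroph" count="{n_each}"
           lo="0 um, 0.5 um" hi="{width} um, 1 um"/>
    <spawn type="random" species="nitrifier" count="{n_each}"
           lo="0 um, 0.5 um" hi="{width} um, 1 um"/>
  </compartment>
</simulation>"""


def run_bm3_skeleton(params: dict[str, float], seed: int = 1, **kwargs) -> Bm3Report:
    """Run the skeleton; returns bulk concentrations and audit residuals."""
    xml = build_bm3_protocol(params, seed=seed, **kwargs)
    sim = loads(xml)
    bulk = sim.compartments["bulk"]
    series: list[dict] = []

    def record(s: Simulation) -> None:
        series.append({"time": s.time, **{k: v for k, v in bulk.solutes.items()}})

    sim.on_step_end.append(record)
    sim.run()
    inactive = sum(1 for a in sim.all_agents() if a.get("inactive"))
    residual = {}
    for s in bulk.solutes:
        accumulated = bulk.volume * bulk.solutes[s] - params["bulk_volume"] * series[0].get(s, bulk.solutes[s]) if series else 0.0
        # closure: in - out + production - accumulation ~ 0
        initial = params[{"SS": "S_S_in", "SN": "S_N_in", "SO2": "S_O2_bulk"}[s]]
        accumulated = bulk.volume * bulk.solutes[s] - params["bulk_volume"] * initial
        lhs = bulk.cum_inflow[s] - bulk.cum_outflow[s] + bulk.cum_production[s]
        scale = max(abs(bulk.cum_inflow[s]), abs(bulk.cum_production[s]), 1e-30)
        residual[s] = abs(lhs - accumulated) / scale
    return Bm3Report(
        bulk_series=series,
        final_bulk=dict(bulk.solutes),
        inactive_count=inactive,
        total_biomass=sim.total_biomass(),
        mass_balance_residual=residual,
    )
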