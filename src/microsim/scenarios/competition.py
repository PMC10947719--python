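"""Rate- vs. yield-strategist biofilm competitions.

Two growth phenotypes compete for oxygen diffusing in from the bulk
above a substratum: the Rate Strategist (RS) grows faster at every
concentration (higher mu_max, same specific affinity mu_max/K, i.e.,
the same initial slope of its Monod kinetics) but converts less of the
consumed resource into biomass; the Yield Strategist (YS) grows more
slowly but more efficiently.  Cooperative (high-yield) clusters convert
the same diffusive flux into more biomass, so spatial segregation --
low initial density -- favors YS while intermediate density mixing
favors RS.

A second variant gives either strategist a filamentous life cycle
(sphere -> rod -> multi-segment filament, torsion-straightened chains),
which lets it grow directionally towards the oxygen source.

Scenarios are generated as protocol documents and run through the
standard loop, so they double as worked examples of the XML dialect.
The default geometry mirrors the study conditions (counts of 5/10/50
cells per strategy, three weeks of growth); reduced ``width``/``t_end``
arguments give desk-scale variants for ensemble statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..protocol import loads
from ..simulation import Simulation

__all__ = [
    "StrategistPair",
    "CompetitionOutcome",
    "build_altruism_protocol",
    "build_filament_protocol",
    "run_altruism_2d",
    "run_filament_cross",
]

MG_PER_L = 1e-3
OXYGEN_DIFFUSIVITY = 7.2e6  # um^2/h
CARBON_DIFFUSIVITY = 2.1e6  # um^2/h, glucose-like


@dataclass
class StrategistPair:
    """Kinetic parameters of the two strategies.

    The constraint mu_max/K_O2 (specific affinity) is equal between the
    two by construction: the rate strategist has both mu_max and K
    doubled.  Yields are per unit oxygen consumed.
    """

    mumax_ys: float = 0.3  # 1/h
    yield_ys: float = 0.5  # fg biomass / fg O2
    affinity_ratio: float = 2.0  # mu_max ratio RS : YS
    ko_ys: float = 0.1 * MG_PER_L  # oxygen half-saturation of YS
    ks_carbon: float = 10.0 * MG_PER_L  # shared carbon half-saturation
    carbon_yield: float = 0.5
    symmetric: bool = False  # identical competitors (null model)

    @property
    def mumax_rs(self) -> float:
        return self.mumax_ys if self.symmetric else self.affinity_ratio * self.mumax_ys

    @property
    def yield_rs(self) -> float:
        return self.yield_ys if self.symmetric else self.yield_ys / self.affinity_ratio

    @property
    def ko_rs(self) -> float:
        # equal specific affinity: mumax/Ko identical for both strategists
        return self.ko_ys if self.symmetric else self.affinity_ratio * self.ko_ys


@dataclass
class CompetitionOutcome:
    seed: int
    times: list[float]
    biomass_a: list[float]  # RS
    biomass_b: list[float]  # YS
    label_a: str = "RS"
    label_b: str = "YS"
    front_a: list[float] = field(default_factory=list)  # max height reached
    front_b: list[float] = field(default_factory=list)

    @property
    def share_a(self) -> float:
        total = self.biomass_a[-1] + self.biomass_b[-1]
        return self.biomass_a[-1] / total if total > 0 else 0.5

    @property
    def share_b(self) -> float:
        return 1.0 - self.share_a

    def winner(self, threshold: float = 0.9) -> str:
        if self.share_a >= threshold:
            return self.label_a
        if self.share_b >= threshold:
            return self.label_b
        return "undecided"


def _growth_reaction_xml(
    name: str, mumax: float, ko: float, ks: float, y_o2: float, y_c: float
) -> str:
    return f"""
        <aspect name="reactions">
          <reaction name="{name}" catalyst="agent"
              rate="mumax*carbon/(Ks+carbon)*oxygen/(Ko+oxygen)*mass">
            <param name="mumax" value="{mumax}"/>
            <param name="Ko" value="{ko}"/>
            <param name="Ks" value="{ks}"/>
            <stoich species="mass" coefficient="1"/>
            <stoich species="oxygen" coefficient="{-1.0 / y_o2}"/>
            <stoich species="carbon" coefficient="{-1.0 / y_c}"/>
          </reaction>
        </aspect>"""


def build_altruism_protocol(
    count_per_strategy: int = 5,
    seed: int = 1,
    width: float = 128.0,
    height: float = 128.0,
    resolution: float = 2.0,
    dt: float = 1.0,
    t_end: float = 504.0,
    pair: StrategistPair | None = None,
    oxygen_bulk: float = 1.0 * MG_PER_L,
    carbon_bulk: float = 2000.0 * MG_PER_L,
) -> str:
    """2D coccoid competition protocol (alternating equidistant start)."""
    pair = pair or StrategistPair()
    division_mass = 300.0
    y0 = 0.5  # spawn just above the substratum
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<simulation name="altruism2d">
  <settings timeStep="{dt} h" endTime="{t_end} h" seed="{seed}"/>
  <speciesLib>
    <module name="coccoid">
      <aspect name="density" value="{150.0 * 0.8164965809277261} fg/um^3"/>
      <aspect name="division mass" value="{division_mass} fg"/>
      <aspect name="division cv" value="0.05"/>
      <aspect name="initial mass" value="{division_mass / 2} fg"/>
    </module>
    <species name="RS">
      <moduleRef name="coccoid"/>{_growth_reaction_xml("growthRS", pair.mumax_rs, pair.ko_rs, pair.ks_carbon, pair.yield_rs, pair.carbon_yield)}
    </species>
    <species name="YS">
      <moduleRef name="coccoid"/>{_growth_reaction_xml("growthYS", pair.mumax_ys, pair.ko_ys, pair.ks_carbon, pair.yield_ys, pair.carbon_yield)}
    </species>
  </speciesLib>
  <compartment name="biofilm" type="spatial" resolution="{resolution} um">
    <shape extents="{width} um, {height} um"/>
    <boundary axis="x" side="min" type="periodic"/>
    <boundary axis="x" side="max" type="periodic"/>
    <boundary axis="y" side="min" type="noflux"/>
    <boundary axis="y" side="max" type="dirichlet">
      <value solute="oxygen" value="{oxygen_bulk} fg/um^3"/>
      <value solute="carbon" value="{carbon_bulk} fg/um^3"/>
    </boundary>
    <solute name="oxygen" initial="{oxygen_bulk} fg/um^3" diffusivity="{OXYGEN_DIFFUSIVITY} um^2/h"/>
    <solute name="carbon" initial="{carbon_bulk} fg/um^3" diffusivity="{CARBON_DIFFUSIVITY} um^2/h"/>
    <process name="reactions" type="reactions" timeStep="{dt} h" priority="0"/>
    <process name="agentUpdates" type="agent_updates" timeStep="{dt} h" priority="1"/>
    <process name="mechanics" type="mechanics" timeStep="{dt} h" priority="2"/>
    <spawn type="alternating" species="RS" speciesB="YS" count="{2 * count_per_strategy}"
           lo="0 um, {y0} um" hi="{width} um, {y0} um"/>
  </compartment>
</simulation>"""


def _filament_species_xml(name: str, filament: bool, pair_block: str) -> str:
    if not filament:
        return f"""
    <species name="{name}">
      <moduleRef name="coccoid"/>{pair_block}
    </species>"""
    return f"""
    <species name="{name}">
      <moduleRef name="coccoid"/>
      <aspect name="differentiation">
        <rule condition="mass &gt;= rodSwitchMass &amp; isRod = 0" module="rod-form"/>
      </aspect>{pair_block}
    </species>"""


def build_filament_protocol(
    morphology_rs: str = "coccus",
    morphology_ys: str = "coccus",
    count_rs: int = 10,
    count_ys: int = 10,
    seed: int = 1,
    width: float = 200.0,
    depth: float = 12.5,
    height: float = 200.0,
    resolution: float = 1.5625,
    dt: float = 1.0,
    t_end: float = 504.0,
    pair: StrategistPair | None = None,
    oxygen_bulk: float = 1.0 * MG_PER_L,
    carbon_bulk: float = 2000.0 * MG_PER_L,
) -> str:
    """Quasi-2D slab (width x depth x height) filament/coccus cross."""
    pair = pair or StrategistPair()
    division_mass = 300.0
    rs_block = _growth_reaction_xml(
        "growthRS", pair.mumax_rs, pair.ko_rs, pair.ks_carbon, pair.yield_rs, pair.carbon_yield
    )
    ys_block = _growth_reaction_xml(
        "growthYS", pair.mumax_ys, pair.ko_ys, pair.ks_carbon, pair.yield_ys, pair.carbon_yield
    )
    species = _filament_species_xml("RS", morphology_rs == "filament", rs_block)
    species += _filament_species_xml("YS", morphology_ys == "filament", ys_block)
    spawns = ""
    z0 = 0.5
    if count_rs and count_ys:
        spawns = (
            f'<spawn type="alternating" species="RS" speciesB="YS" '
            f'count="{count_rs + count_ys}" lo="0 um, {depth / 2} um, {z0} um" '
            f'hi="{width} um, {depth / 2} um, {z0} um"/>'
        )
    elif count_rs or count_ys:
        only = "RS" if count_rs else "YS"
        n = count_rs or count_ys
        spawns = (
            f'<spawn type="distributed" species="{only}" count="{n}" '
            f'lo="0 um, {depth / 2} um, {z0} um" hi="{width} um, {depth / 2} um, {z0} um"/>'
        )
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<simulation name="filamentCross">
  <settings timeStep="{dt} h" endTime="{t_end} h" seed="{seed}"/>
  <speciesLib>
    <module name="coccoid">
      <aspect name="density" value="150 fg/um^3"/>
      <aspect name="division mass" value="{division_mass} fg"/>
      <aspect name="division cv" value="0.05"/>
      <aspect name="initial mass" value="{division_mass / 2} fg"/>
      <aspect name="rodSwitchMass" value="{0.7 * division_mass} fg"/>
      <aspect name="isRod" value="0"/>
    </module>
    <module name="rod-form">
      <aspect name="morphology" value="bacillus"/>
      <aspect name="isRod" value="1"/>
      <aspect name="filament" value="true"/>
      <aspect name="rod radius" value="0.4 um"/>
      <aspect name="division mass" value="{1.2 * division_mass} fg"/>
    </module>{species}
  </speciesLib>
  <compartment name="biofilm" type="spatial" resolution="{resolution} um">
    <shape extents="{width} um, {depth} um, {height} um"/>
    <boundary axis="x" side="min" type="periodic"/>
    <boundary axis="x" side="max" type="periodic"/>
    <boundary axis="y" side="min" type="periodic"/>
    <boundary axis="y" side="max" type="periodic"/>
    <boundary axis="z" side="min" type="noflux"/>
    <boundary axis="z" side="max" type="dirichlet">
      <value solute="oxygen" value="{oxygen_bulk} fg/um^3"/>
      <value solute="carbon" value="{carbon_bulk} fg/um^3"/>
    </boundary>
    <solute name="oxygen" initial="{oxygen_bulk} fg/um^3" diffusivity="{OXYGEN_DIFFUSIVITY} um^2/h"/>
    <solute name="carbon" initial="{carbon_bulk} fg/um^3" diffusivity="{CARBON_DIFFUSIVITY} um^2/h"/>
    <process name="reactions" type="reactions" timeStep="{dt} h" priority="0"/>
    <process name="agentUpdates" type="agent_updates" timeStep="{dt} h" priority="1"/>
    <process name="mechanics" type="mechanics" timeStep="{dt} h" priority="2">
      <param name="max_iterations" value="250"/>
    </process>
    {spawns}
  </compartment>
</simulation>"""


def _run_competition(xml: str, seed: int, labels=("RS", "YS")) -> CompetitionOutcome:
    sim = loads(xml)
    comp = sim.compartments["biofilm"]
    times: list[float] = []
    mass_a: list[float] = []
    mass_b: list[float] = []
    front_a: list[float] = []
    front_b: list[float] = []
    vertical = comp.dim - 1

    def front(species: str) -> float:
        heights = [
            float(a.center[vertical]) for a in comp.agents if a.species == species
        ]
        return max(heights) if heights else 0.0

    def record(s: Simulation) -> None:
        times.append(s.time)
        mass_a.append(s.total_biomass(labels[0]))
        mass_b.append(s.total_biomass(labels[1]))
        front_a.append(front(labels[0]))
        front_b.append(front(labels[1]))

    sim.on_step_end.append(record)
    record(sim)
    sim.run()
    return CompetitionOutcome(
        seed=seed, times=times, biomass_a=mass_a, biomass_b=mass_b,
        label_a=labels[0], label_b=labels[1], front_a=front_a, front_b=front_b,
    )


def run_altruism_2d(
    count_per_strategy: int = 5, seed: int = 1, **kwargs
) -> CompetitionOutcome:
    """Run the 2D coccoid competition; see :func:`build_altruism_protocol`."""
    xml = build_altruism_protocol(count_per_strategy, seed, **kwargs)
    return _run_competition(xml, seed)


def run_filament_cross(
    morphology_rs: str = "coccus",
    morphology_ys: str = "coccus",
    seed: int = 1,
    **kwargs,
) -> CompetitionOutcome:
    """Run a morphology cross; see :func:`build_filament_protocol`."""
    xml = build_filament_protocol(morphology_rs, morphology_ys, seed=seed, **kwargs)
    return _run_competition(xml, seed)
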