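"""Protocol documents: hierarchical XML model specification and snapshots.

A protocol file declares the whole model: simulator settings, the
species library of reusable aspect modules, compartments with their
shape, solutes, boundaries, reactions, processes and initial-state
spawners.  All quantities carry units and are converted to base units
(um, fg, h) on load.  Snapshots use the same schema plus the full
dynamic state (agent inventories, solute fields, random-stream state,
schedule state), so any snapshot is itself a valid input that continues
the run with consecutive random numbers.

Sketch of the dialect::

    <simulation name="demo">
      <settings timeStep="1 h" endTime="24 h" seed="42"/>
      <speciesLib>
        <module name="coccoid">
          <aspect name="density" value="150 fg/um^3"/>
        </module>
        <species name="bacterium">
          <moduleRef name="coccoid"/>
          <aspect name="reactions">
            <reaction name="growth" catalyst="agent"
                      rate="mumax*carbon/(Ks+carbon)*oxygen/(Ko+oxygen)*mass">
              <param name="mumax" value="0.6 /h"/>
              <stoich species="mass" coefficient="1"/>
              <stoich species="carbon" coefficient="-2"/>
            </reaction>
          </aspect>
        </species>
      </speciesLib>
      <compartment name="biofilm" type="spatial" resolution="2 um">
        <shape extents="64 um, 64 um"/>
        <boundary axis="x" side="min" type="periodic"/>
        ...
        <solute name="oxygen" initial="1 mg/L" diffusivity="7.2e6 um^2/h"/>
        <process name="reactions" type="reactions" timeStep="1 h"/>
        <spawn type="random" species="bacterium" count="30"
               lo="0 um, 0 um" hi="64 um, 2 um"/>
      </compartment>
    </simulation>
"""

from __future__ import annotations

import io
import itertools
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import agents as agents_mod
from .agents import Agent, MassPoint, SpineLink, TorsionHinge, update_geometry
from .expressions import parse_arithmetic, parse_logic
from .initialization import SpawnerSpec, spawn_alternating, spawn_distributed, spawn_random
from .reactions import Reaction
from .schedule import ProcessSchedule
from .simulation import Simulation
from .spatial import BoundarySpec, SoluteField, SpatialCompartment
from .species import SpeciesLibrary
from .units import UnitError, parse_quantity, to_base
from .wellmixed import Flow, WellMixedCompartment

__all__ = [
    "ProtocolError",
    "load_protocol",
    "loads",
    "save_snapshot",
    "load_snapshot",
]

_AXES = {"x": 0, "y": 1, "z": 2, "0": 0, "1": 1, "2": 2}
_SIDES = {"min": 0, "max": 1, "0": 0, "1": 1}


class ProtocolError(ValueError):
    """Schema / configuration error naming the offending element path."""


def _qty(element: ET.Element, attr: str, path: str, default=None) -> float:
    raw = element.get(attr)
    if raw is None:
        if default is not None:
            return default
        raise ProtocolError(f"{path}: missing mandatory attribute {attr!r}")
    try:
        return to_base(raw)
    except UnitError as exc:
        raise ProtocolError(f"{path}@{attr}: {exc}") from exc


def _qty_list(element: ET.Element, attr: str, path: str) -> list[float]:
    raw = element.get(attr)
    if raw is None:
        raise ProtocolError(f"{path}: missing mandatory attribute {attr!r}")
    try:
        return [to_base(part.strip()) for part in raw.split(",")]
    except UnitError as exc:
        raise ProtocolError(f"{path}@{attr}: {exc}") from exc


_KNOWN = {
    "simulation": {"settings", "rng", "schedule", "speciesLib", "compartment"},
    "speciesLib": {"module", "species"},
    "module": {"aspect"},
    "species": {"moduleRef", "aspect"},
    "aspect": {"reaction", "rule"},
    "compartment": {
        "shape",
        "boundary",
        "solute",
        "reaction",
        "flow",
        "process",
        "spawn",
        "parameter",
        "agents",
        "links",
        "audit",
    },
    "reaction": {"param", "stoich"},
    "boundary": {"value"},
    "flow": {"concentration"},
    "process": {"param"},
    "agents": {"agent"},
    "agent": {"point", "aspect"},
    "links": {"link", "hinge"},
}


def _check_children(element: ET.Element, path: str) -> None:
    allowed = _KNOWN.get(element.tag)
    if allowed is None:
        return
    for child in element:
        if child.tag not in allowed:
            raise ProtocolError(f"{path}/{child.tag}: unknown element")


def _parse_aspect(element: ET.Element, path: str) -> tuple[str, Any]:
    name = element.get("name")
    if name is None:
        raise ProtocolError(f"{path}: aspect without name")
    children = list(element)
    if children and children[0].tag == "reaction":
        return name, [_parse_reaction(c, f"{path}/{name}") for c in children]
    if children and children[0].tag == "rule":
        rules = []
        for c in children:
            rule: dict[str, Any] = {"condition": c.get("condition", "1 = 1")}
            if c.get("module"):
                rule["module"] = c.get("module")
            overrides = {}
            for k, v in c.attrib.items():
                if k in ("condition", "module"):
                    continue
                overrides[k] = _maybe_number(v)
            if overrides:
                rule["aspects"] = overrides
            rules.append(rule)
        return name, rules
    raw = element.get("value")
    if raw is None:
        raise ProtocolError(f"{path}/{name}: aspect without value")
    return name, _maybe_number(raw)


def _maybe_number(raw: str) -> Any:
    if raw in ("true", "false"):
        return raw == "true"
    try:
        return parse_quantity(raw).value
    except (UnitError, ValueError):
        return raw


def _parse_reaction(element: ET.Element, path: str) -> Reaction:
    name = element.get("name", "reaction")
    rate = element.get("rate")
    if rate is None:
        raise ProtocolError(f"{path}/{name}: reaction without rate expression")
    params = {}
    stoich = {}
    for child in element:
        if child.tag == "param":
            params[child.get("name")] = to_base(child.get("value"))
        elif child.tag == "stoich":
            stoich[child.get("species")] = float(child.get("coefficient"))
        else:
            raise ProtocolError(f"{path}/{name}/{child.tag}: unknown element")
    return Reaction(
        name=name,
        stoichiometry=stoich,
        rate=parse_arithmetic(rate),
        catalyst=element.get("catalyst", "environment"),
        params=params,
    )


@dataclass
class ProtocolDocument:
    """Fully resolved model specification (base units everywhere)."""

    name: str
    global_dt: float
    seed: int
    end_time: float | None
    output_interval: float | None
    library: SpeciesLibrary
    compartments: list[dict]
    root: ET.Element  # raw tree (for state restoration)


def load_protocol(text: str) -> ProtocolDocument:
    """Parse and resolve a protocol document (or snapshot)."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ProtocolError(f"malformed XML: {exc}") from exc
    if root.tag != "simulation":
        raise ProtocolError(f"/{root.tag}: expected root element 'simulation'")
    _check_children(root, "/simulation")
    settings = root.find("settings")
    if settings is None:
        raise ProtocolError("/simulation: missing settings element")
    global_dt = _qty(settings, "timeStep", "/simulation/settings")
    seed = int(settings.get("seed", "1"))
    end_time = (
        to_base(settings.get("endTime")) if settings.get("endTime") else None
    )
    out_int = (
        to_base(settings.get("outputInterval"))
        if settings.get("outputInterval")
        else None
    )

    library = SpeciesLibrary()
    lib_el = root.find("speciesLib")
    if lib_el is not None:
        _check_children(lib_el, "/simulation/speciesLib")
        for mod in lib_el.findall("module"):
            _check_children(mod, f"/speciesLib/module[{mod.get('name')}]")
            aspects = dict(
                _parse_aspect(a, f"/speciesLib/module[{mod.get('name')}]")
                for a in mod.findall("aspect")
            )
            library.add_module(mod.get("name"), aspects)
        for spc in lib_el.findall("species"):
            _check_children(spc, f"/speciesLib/species[{spc.get('name')}]")
            mods = [m.get("name") for m in spc.findall("moduleRef")]
            aspects = dict(
                _parse_aspect(a, f"/speciesLib/species[{spc.get('name')}]")
                for a in spc.findall("aspect")
            )
            library.add_species(spc.get("name"), mods, aspects)

    compartments = []
    for comp_el in root.findall("compartment"):
        compartments.append(_parse_compartment(comp_el, library))
    return ProtocolDocument(
        name=root.get("name", "simulation"),
        global_dt=global_dt,
        seed=seed,
        end_time=end_time,
        output_interval=out_int,
        library=library,
        compartments=compartments,
        root=root,
    )


def _parse_compartment(el: ET.Element, library: SpeciesLibrary) -> dict:
    name = el.get("name", "compartment")
    path = f"/simulation/compartment[{name}]"
    _check_children(el, path)
    ctype = el.get("type", "wellMixed")
    spec: dict[str, Any] = {"name": name, "type": ctype, "element": el}
    spec["parameters"] = {
        p.get("name"): to_base(p.get("value")) for p in el.findall("parameter")
    }
    spec["solutes"] = []
    for s in el.findall("solute"):
        spec["solutes"].append(
            {
                "name": s.get("name"),
                "initial": _qty(s, "initial", f"{path}/solute", default=0.0),
                "diffusivity": (
                    to_base(s.get("diffusivity")) if s.get("diffusivity") else None
                ),
                "biofilm_factor": float(s.get("biofilmDiffusivityFactor", "1")),
            }
        )
    spec["reactions"] = [
        _parse_reaction(r, path) for r in el.findall("reaction")
    ]
    spec["processes"] = []
    for i, p in enumerate(el.findall("process")):
        params = {
            q.get("name"): _maybe_number(q.get("value")) for q in p.findall("param")
        }
        spec["processes"].append(
            {
                "name": p.get("name", f"{name}-process{i}"),
                "kind": p.get("type"),
                "time_step": to_base(p.get("timeStep")) if p.get("timeStep") else None,
                "priority": int(p.get("priority")) if p.get("priority") else None,
                "params": params,
            }
        )
    spec["spawns"] = []
    for sp in el.findall("spawn"):
        spec["spawns"].append(
            {
                "kind": sp.get("type", "random"),
                "species": sp.get("species"),
                "species_b": sp.get("speciesB"),
                "count": int(sp.get("count", "0")),
                "lo": _qty_list(sp, "lo", f"{path}/spawn") if sp.get("lo") else None,
                "hi": _qty_list(sp, "hi", f"{path}/spawn") if sp.get("hi") else None,
                "interval": to_base(sp.get("interval")) if sp.get("interval") else None,
            }
        )
        for key in ("species",):
            sname = spec["spawns"][-1][key]
            if sname and sname not in library:
                raise ProtocolError(f"{path}/spawn: unknown species {sname!r}")
    if ctype == "spatial":
        shape = el.find("shape")
        if shape is None:
            raise ProtocolError(f"{path}: spatial compartment without shape")
        spec["extents"] = _qty_list(shape, "extents", f"{path}/shape")
        spec["resolution"] = _qty(el, "resolution", path)
        spec["thickness"] = _qty(el, "thickness", path, default=1.0)
        spec["scale_factor"] = float(el.get("scaleFactor", "1"))
        spec["scale_2d"] = el.get("scale2d", "true") != "false"
        spec["boundaries"] = {}
        for b in el.findall("boundary"):
            ax = _AXES.get(b.get("axis", ""))
            side = _SIDES.get(b.get("side", ""))
            if ax is None or side is None:
                raise ProtocolError(f"{path}/boundary: need axis and side")
            values = {
                v.get("solute"): to_base(v.get("value")) for v in b.findall("value")
            }
            spec["boundaries"][(ax, side)] = BoundarySpec(
                kind=b.get("type", "noflux"),
                values=values,
                compartment=b.get("compartment"),
            )
    else:
        spec["volume"] = _qty(el, "volume", path, default=1e9)
        spec["flows"] = []
        for f in el.findall("flow"):
            conc = {
                c.get("solute"): to_base(c.get("value"))
                for c in f.findall("concentration")
            }
            spec["flows"].append(
                Flow(
                    kind=f.get("kind"),
                    rate=_qty(f, "rate", f"{path}/flow"),
                    concentrations=conc,
                    retain_agents=f.get("retainAgents", "false") == "true",
                )
            )
    return spec


# ---------------------------------------------------------------------------
# building a live simulation
# ---------------------------------------------------------------------------


def build_simulation(doc: ProtocolDocument) -> Simulation:
    sim = Simulation(
        global_dt=doc.global_dt,
        seed=doc.seed,
        end_time=doc.end_time,
        name=doc.name,
    )
    sim.library = doc.library
    for cspec in doc.compartments:
        if cspec["type"] == "spatial":
            comp = SpatialCompartment(
                cspec["name"],
                tuple(cspec["extents"]),
                cspec["resolution"],
                boundaries=cspec.get("boundaries"),
                thickness=cspec.get("thickness", 1.0),
                scale_factor=cspec.get("scale_factor", 1.0),
                parameters=cspec.get("parameters"),
                scale_2d=cspec.get("scale_2d", True),
            )
            for s in cspec["solutes"]:
                if s["diffusivity"] is None:
                    raise ProtocolError(
                        f"solute {s['name']!r} in spatial compartment needs a diffusivity"
                    )
                comp.add_solute(
                    SoluteField(
                        s["name"], s["diffusivity"],
                        biofilm_diffusivity_factor=s["biofilm_factor"],
                    ),
                    initial=s["initial"],
                )
            for rxn in cspec["reactions"]:
                comp.add_reaction(rxn)
        else:
            comp = WellMixedCompartment(
                cspec["name"],
                volume=cspec.get("volume", 1e9),
                solutes={s["name"]: s["initial"] for s in cspec["solutes"]},
                flows=cspec.get("flows"),
                reactions=cspec["reactions"],
                parameters=cspec.get("parameters"),
            )
        sim.add_compartment(comp)
        thickness = getattr(comp, "thickness", 1.0)
        scale_2d = getattr(comp, "scale_2d", True)
        for spawn in cspec["spawns"]:
            if spawn["lo"] is None:
                if cspec["type"] == "spatial":
                    lo = [0.0] * len(cspec["extents"])
                    hi = list(cspec["extents"])
                else:
                    lo = hi = [0.0]
            else:
                lo, hi = spawn["lo"], spawn["hi"]
            sspec = SpawnerSpec(
                species=spawn["species"],
                count=spawn["count"],
                region_lo=tuple(lo),
                region_hi=tuple(hi),
                interval=spawn["interval"],
                kind=spawn["kind"],
            )
            if spawn["kind"] == "random":
                born = spawn_random(sspec, sim.rng, doc.library, thickness, scale_2d)
            elif spawn["kind"] == "distributed":
                born = spawn_distributed(sspec, doc.library, thickness, scale_2d)
            elif spawn["kind"] == "alternating":
                born = spawn_alternating(
                    spawn["species"], spawn["species_b"], spawn["count"],
                    lo, hi, doc.library, thickness, scale_2d,
                )
            else:
                raise ProtocolError(f"unknown spawner type {spawn['kind']!r}")
            comp.agents.extend(born)
        for proc in cspec["processes"]:
            sim.add_process(
                proc["name"],
                cspec["name"],
                proc["kind"],
                time_step=proc["time_step"],
                priority=proc["priority"],
                **proc["params"],
            )
    _restore_state(sim, doc.root)
    return sim


def loads(text: str) -> Simulation:
    """Parse a protocol or snapshot and build the live simulation."""
    return build_simulation(load_protocol(text))


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------


def _restore_state(sim: Simulation, root: ET.Element) -> None:
    """Apply snapshot-only elements (rng, schedule, agents, fields, time)."""
    settings = root.find("settings")
    if settings is not None and settings.get("time"):
        sim.time = float(settings.get("time"))
    rng_el = root.find("rng")
    if rng_el is not None and rng_el.text:
        try:
            state = json.loads(rng_el.text)
        except json.JSONDecodeError as exc:
            raise ProtocolError(f"corrupted snapshot: bad rng state: {exc}") from exc
        sim.rng.bit_generator.state = state
    sched_el = root.find("schedule")
    if sched_el is not None:
        rows = [
            {
                "process_id": e.get("process"),
                "due": float(e.get("due")),
                "priority": int(e.get("priority")),
                "insertion": int(e.get("insertion")),
                "time_step": float(e.get("timeStep")),
            }
            for e in sched_el.findall("entry")
        ]
        sim.schedule = ProcessSchedule.from_state(rows)
    max_id = 0
    for comp_el in root.findall("compartment"):
        comp = sim.compartments[comp_el.get("name")]
        agents_el = comp_el.find("agents")
        if agents_el is None:
            continue
        comp.agents = []
        for a_el in agents_el.findall("agent"):
            points = [
                MassPoint(
                    np.array([float(v) for v in p.get("position").split(",")]),
                    float(p.get("mass")),
                )
                for p in a_el.findall("point")
            ]
            aspects = dict(
                _parse_aspect(x, "agent") for x in a_el.findall("aspect")
            )
            agent = Agent(
                a_el.get("species"),
                points,
                kind=a_el.get("kind", "coccus"),
                aspects=aspects,
                library=sim.library,
                agent_id=int(a_el.get("id")),
                parent_id=int(a_el.get("parent")) if a_el.get("parent") else None,
            )
            update_geometry(
                agent,
                getattr(comp, "thickness", 1.0),
                getattr(comp, "scale_2d", True),
            )
            max_id = max(max_id, agent.id)
            comp.agents.append(agent)
        links_el = comp_el.find("links")
        if links_el is not None and hasattr(comp, "registry"):
            comp.registry.links = [
                SpineLink(
                    int(l.get("agentA")), int(l.get("pointA")),
                    int(l.get("agentB")), int(l.get("pointB")),
                    float(l.get("rest")), float(l.get("k")),
                )
                for l in links_el.findall("link")
            ]
            comp.registry.hinges = [
                TorsionHinge(
                    tuple(
                        (int(pair.split(":")[0]), int(pair.split(":")[1]))
                        for pair in h.get("refs").split(";")
                    ),
                    stiffness=float(h.get("kappa")),
                    rest_angle=float(h.get("rest")),
                )
                for h in links_el.findall("hinge")
            ]
        for s_el in comp_el.findall("solute"):
            sname = s_el.get("name")
            if s_el.get("state") is not None:
                if isinstance(comp, SpatialCompartment):
                    values = np.array(
                        [float(v) for v in s_el.get("state").split(",")]
                    )
                    comp.solutes[sname].field = values.reshape(comp.shape)
                else:
                    comp.solutes[sname] = float(s_el.get("state"))
        if isinstance(comp, WellMixedCompartment) and comp_el.get("currentVolume"):
            comp.volume = float(comp_el.get("currentVolume"))
    if max_id:
        agents_mod._id_counter = itertools.count(max_id + 1)


def _fmt(x: float) -> str:
    return repr(float(x))


def _aspect_xml(parent: ET.Element, name: str, value: Any) -> None:
    el = ET.SubElement(parent, "aspect", name=name)
    if isinstance(value, list) and value and isinstance(value[0], Reaction):
        for rxn in value:
            r_el = ET.SubElement(
                el,
                "reaction",
                name=rxn.name,
                rate=rxn.rate.source,
                catalyst=rxn.catalyst,
            )
            for k, v in rxn.params.items():
                ET.SubElement(r_el, "param", name=k, value=_fmt(v))
            for k, v in rxn.stoichiometry.items():
                ET.SubElement(r_el, "stoich", species=k, coefficient=_fmt(v))
    elif isinstance(value, list):
        for rule in value:
            attrs = {"condition": str(rule.get("condition"))}
            if rule.get("module"):
                attrs["module"] = rule["module"]
            for k, v in rule.get("aspects", {}).items():
                attrs[k] = _fmt(v) if isinstance(v, (int, float)) else str(v)
            ET.SubElement(el, "rule", **attrs)
    elif isinstance(value, bool):
        el.set("value", "true" if value else "false")
    elif isinstance(value, (int, float)):
        el.set("value", _fmt(value))
    else:
        el.set("value", str(value))


def save_snapshot(sim: Simulation) -> str:
    """Serialize the full state; loading reproduces the run bit-for-bit."""
    root = ET.Element("simulation", name=sim.name)
    ET.SubElement(
        root,
        "settings",
        timeStep=_fmt(sim.global_dt),
        seed=str(sim.seed),
        time=_fmt(sim.time),
        **({"endTime": _fmt(sim.end_time)} if sim.end_time is not None else {}),
    )
    rng_el = ET.SubElement(root, "rng")
    rng_el.text = json.dumps(sim.rng.bit_generator.state)
    sched_el = ET.SubElement(root, "schedule")
    for row in sim.schedule.state():
        ET.SubElement(
            sched_el,
            "entry",
            process=row["process_id"],
            due=_fmt(row["due"]),
            priority=str(row["priority"]),
            insertion=str(row["insertion"]),
            timeStep=_fmt(row["time_step"]),
        )
    lib_el = ET.SubElement(root, "speciesLib")
    for mname, aspects in sim.library.modules.items():
        m_el = ET.SubElement(lib_el, "module", name=mname)
        for k, v in aspects.items():
            _aspect_xml(m_el, k, v)
    for sname, sdef in sim.library.species.items():
        s_el = ET.SubElement(lib_el, "species", name=sname)
        for m in sdef.modules:
            ET.SubElement(s_el, "moduleRef", name=m)
        for k, v in sdef.aspects.items():
            _aspect_xml(s_el, k, v)
    for comp in sim.compartments.values():
        if isinstance(comp, SpatialCompartment):
            c_el = ET.SubElement(
                root,
                "compartment",
                name=comp.name,
                type="spatial",
                resolution=_fmt(comp.resolution),
                thickness=_fmt(comp.thickness),
                scaleFactor=_fmt(comp.scale_factor),
                scale2d="true" if comp.scale_2d else "false",
            )
            ET.SubElement(
                c_el, "shape", extents=", ".join(_fmt(e) for e in comp.extents)
            )
            for (ax, side), bspec in sorted(comp.boundaries.items()):
                b_el = ET.SubElement(
                    c_el,
                    "boundary",
                    axis=str(ax),
                    side=str(side),
                    type=bspec.kind,
                )
                if bspec.compartment:
                    b_el.set("compartment", bspec.compartment)
                for sname, v in bspec.values.items():
                    ET.SubElement(b_el, "value", solute=sname, value=_fmt(v))
            for sname, sol in comp.solutes.items():
                ET.SubElement(
                    c_el,
                    "solute",
                    name=sname,
                    diffusivity=_fmt(sol.diffusivity),
                    biofilmDiffusivityFactor=_fmt(sol.biofilm_diffusivity_factor),
                    state=", ".join(_fmt(v) for v in sol.field.ravel()),
                )
        else:
            c_el = ET.SubElement(
                root,
                "compartment",
                name=comp.name,
                type="wellMixed",
                volume=_fmt(comp.volume),
                currentVolume=_fmt(comp.volume),
            )
            for f in comp.flows:
                f_el = ET.SubElement(
                    c_el,
                    "flow",
                    kind=f.kind,
                    rate=_fmt(f.rate),
                    retainAgents="true" if f.retain_agents else "false",
                )
                for sname, v in f.concentrations.items():
                    ET.SubElement(f_el, "concentration", solute=sname, value=_fmt(v))
            for sname, v in comp.solutes.items():
                ET.SubElement(c_el, "solute", name=sname, state=_fmt(v))
        for k, v in getattr(comp, "parameters", {}).items():
            ET.SubElement(c_el, "parameter", name=k, value=_fmt(v))
        for rxn in getattr(comp, "reactions", []):
            r_el = ET.SubElement(
                c_el, "reaction", name=rxn.name, rate=rxn.rate.source,
                catalyst=rxn.catalyst,
            )
            for k, v in rxn.params.items():
                ET.SubElement(r_el, "param", name=k, value=_fmt(v))
            for k, v in rxn.stoichiometry.items():
                ET.SubElement(r_el, "stoich", species=k, coefficient=_fmt(v))
        a_parent = ET.SubElement(c_el, "agents")
        for agent in getattr(comp, "agents", []):
            a_el = ET.SubElement(
                a_parent,
                "agent",
                id=str(agent.id),
                species=agent.species,
                kind=agent.kind,
            )
            if agent.parent_id is not None:
                a_el.set("parent", str(agent.parent_id))
            for p in agent.points:
                ET.SubElement(
                    a_el,
                    "point",
                    position=", ".join(_fmt(v) for v in p.position),
                    mass=_fmt(p.mass),
                )
            for k, v in agent.aspects.items():
                if k.startswith("_"):
                    continue
                _aspect_xml(a_el, k, v)
        registry = getattr(comp, "registry", None)
        if registry is not None and (registry.links or registry.hinges):
            l_el = ET.SubElement(c_el, "links")
            for link in registry.links:
                ET.SubElement(
                    l_el,
                    "link",
                    agentA=str(link.agent_a),
                    pointA=str(link.point_a),
                    agentB=str(link.agent_b),
                    pointB=str(link.point_b),
                    rest=_fmt(link.rest_length),
                    k=_fmt(link.stiffness),
                )
            for hinge in registry.hinges:
                ET.SubElement(
                    l_el,
                    "hinge",
                    refs=";".join(f"{a}:{p}" for a, p in hinge.refs),
                    kappa=_fmt(hinge.stiffness),
                    rest=_fmt(hinge.rest_angle),
                )
    # processes (re-created on load)
    for spec in sim.processes.values():
        comp_el = root.find(f"compartment[@name='{spec.compartment}']")
        p_el = ET.SubElement(
            comp_el,
            "process",
            name=spec.name,
            type=spec.kind,
            timeStep=_fmt(spec.time_step),
            priority=str(spec.priority),
        )
        for k, v in spec.params.items():
            if isinstance(v, (int, float, str, bool)):
                ET.SubElement(
                    p_el, "param", name=k,
                    value=_fmt(v) if isinstance(v, (int, float)) else str(v),
                )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def load_snapshot(text: str) -> Simulation:
    """Load a snapshot; corrupted documents raise :class:`ProtocolError`."""
    sim = loads(text)
    # schedule restored by _restore_state; nothing extra to do
    return sim
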