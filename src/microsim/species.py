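"""Species library: reusable aspect modules.

Agents carry "aspects" -- named properties and behaviors (mass, density,
division mass, reaction list, morphology, switch rules, ...).  Aspects
shared by all agents of a species live in the species library so they
are stored once and looked up.  A species references an ordered list of
modules; a later module overrides an earlier one for the same aspect
name ("last reference wins"), and an aspect defined locally on the
species overrides any module.  Aspects set directly on an individual
agent override everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["SpeciesLibrary", "SpeciesDefinition"]


class SpeciesError(KeyError):
    pass


@dataclass
class SpeciesDefinition:
    name: str
    modules: list[str] = field(default_factory=list)
    aspects: dict[str, Any] = field(default_factory=dict)


class SpeciesLibrary:
    def __init__(self) -> None:
        self.modules: dict[str, dict[str, Any]] = {}
        self.species: dict[str, SpeciesDefinition] = {}

    def add_module(self, name: str, aspects: dict[str, Any]) -> None:
        self.modules[name] = dict(aspects)

    def add_species(
        self,
        name: str,
        modules: list[str] | None = None,
        aspects: dict[str, Any] | None = None,
    ) -> None:
        for mod in modules or []:
            if mod not in self.modules:
                raise SpeciesError(f"species {name!r} references unknown module {mod!r}")
        self.species[name] = SpeciesDefinition(
            name, list(modules or []), dict(aspects or {})
        )

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def resolve(self, species_name: str) -> dict[str, Any]:
        """Merge module aspects (in reference order, last wins) with local aspects."""
        try:
            spec = self.species[species_name]
        except KeyError:
            raise SpeciesError(f"unknown species {species_name!r}") from None
        merged: dict[str, Any] = {}
        for mod in spec.modules:
            merged.update(self.modules[mod])
        merged.update(spec.aspects)
        return merged

    def lookup(self, species_name: str, aspect: str, default: Any = None) -> Any:
        return self.resolve(species_name).get(aspect, default)
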