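"""Agent geometry, growth, division, differentiation and 2D scaling."""

import math

import numpy as np
import pytest

from conftest import make_coccus, make_rod
from microsim.agents import (
    BACILLUS,
    COCCUS,
    Agent,
    LinkRegistry,
    MassPoint,
    differentiate,
    divide,
    grow,
    radius_from_volume,
    scale_density_2d,
    sphere_circle_packing_factor,
    spherocylinder_length,
    spherocylinder_volume,
    update_geometry,
    volume_from_radius,
)


class TestRadiusFromVolume:
    def test_unit_sphere(self):
        assert radius_from_volume(4 * math.pi / 3) == pytest.approx(1.0)

    def test_scaling(self):
        assert radius_from_volume(32 * math.pi / 3) == pytest.approx(2.0)

    def test_inverse_roundtrip(self, rng):
        for v in rng.uniform(0.01, 100.0, size=100):
            assert volume_from_radius(radius_from_volume(v)) == pytest.approx(
                v, rel=1e-12
            )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            radius_from_volume(0.0)


class TestGrow:
    def test_zero_rate_leaves_geometry(self):
        a = make_coccus([0, 0, 0])
        r0 = a.radius
        grow(a, 1.0, 0.0)
        update_geometry(a)
        assert a.radius == r0

    def test_mass_doubling_scales_radius_cuberoot(self):
        a = make_coccus([0, 0, 0], mass=300.0)
        r0 = a.radius
        grow(a, 1.0, 300.0)
        update_geometry(a)
        assert a.radius == pytest.approx(r0 * 2 ** (1 / 3))

    def test_rod_grows_in_length_at_constant_radius(self):
        rod = make_rod([0, 0, 0], [2, 0, 0], mass=600.0)
        r0, l0 = rod.radius, rod.rest_length
        # oracle: invert the spherocylinder volume map directly
        expected = spherocylinder_length(2 * 600.0 / 150.0, r0)
        grow(rod, 1.0, 600.0)
        update_geometry(rod)
        assert rod.radius == r0
        assert rod.rest_length == pytest.approx(expected, rel=1e-9)
        assert rod.rest_length > l0

    def test_decay_past_zero_flags_inactive(self):
        a = make_coccus([0, 0, 0], mass=10.0)
        grow(a, 1.0, -20.0)
        assert a.aspects.get("inactive") == 1.0
        assert a.mass > 0


class TestDensityConstancy:
    def test_coccus_density_invariant_under_growth(self, rng):
        a = make_coccus([0, 0, 0], mass=200.0)
        for rate in rng.uniform(-20, 100, size=20):
            grow(a, 1.0, float(rate))
            update_geometry(a)
            vol = volume_from_radius(a.radius)
            assert a.mass / vol == pytest.approx(a.density, rel=1e-9)

    def test_rod_density_invariant_under_growth(self, rng):
        rod = make_rod([0, 0, 0], [1, 0, 0], mass=400.0)
        for rate in rng.uniform(0, 200, size=10):
            grow(rod, 1.0, float(rate))
            update_geometry(rod)
            vol = spherocylinder_volume(rod.radius, rod.rest_length)
            assert rod.mass / vol == pytest.approx(rod.density, rel=1e-9)


class TestDivide:
    def test_zero_cv_gives_exact_halves(self, rng):
        a = make_coccus([5.0, 5.0], mass=300.0, **{"division cv": 0.0})
        d = divide(a, rng)
        assert a.mass == pytest.approx(150.0)
        assert d.mass == pytest.approx(150.0)

    def test_mass_conserved_to_machine_precision(self, rng):
        for _ in range(50):
            m0 = float(rng.uniform(100, 500))
            a = make_coccus([5.0, 5.0], mass=m0, **{"division cv": 0.1})
            d = divide(a, rng)
            assert a.mass + d.mass == pytest.approx(m0, abs=1e-12 * m0)

    def test_truncated_normal_support_and_mean(self, rng):
        """10^4 draws at CV 0.1: mean fraction ~ 0.5, all within +/- 2 sigma."""
        cv = 0.1
        sigma = 0.5 * cv
        fracs = []
        for _ in range(10_000):
            a = make_coccus([0.0, 0.0], mass=300.0, **{"division cv": cv})
            d = divide(a, rng)
            fracs.append(d.mass / 300.0)
        fracs = np.array(fracs)
        assert np.all(fracs >= 0.5 - 2 * sigma - 1e-12)
        assert np.all(fracs <= 0.5 + 2 * sigma + 1e-12)
        # truncated normal keeps the symmetric mean; 3 s.e. band
        se = fracs.std() / math.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se + 1e-4

    def test_coccus_daughters_displaced_oppositely(self, rng):
        a = make_coccus([5.0, 5.0], mass=300.0, **{"division cv": 0.0})
        center0 = a.center.copy()
        d = divide(a, rng)
        u1 = a.center - center0
        u2 = d.center - center0
        # opposite directions, each displaced by its own radius
        assert np.dot(u1, u2) < 0
        assert np.linalg.norm(u1) == pytest.approx(a.radius, rel=1e-9)
        assert np.linalg.norm(u2) == pytest.approx(d.radius, rel=1e-9)

    def test_rod_splits_along_axis_with_compression(self, rng):
        rod = make_rod([0, 0, 0], [4, 0, 0], mass=600.0, **{"division cv": 0.0})
        d = divide(rod, rng)
        assert rod.kind == BACILLUS and d.kind == BACILLUS
        assert rod.mass + d.mass == pytest.approx(600.0)
        # new inner points sit on opposite sides of the old center of gravity
        inner_mother = rod.points[0].position
        inner_daughter = d.points[0].position
        assert inner_mother[0] > 2.0 > inner_daughter[0]
        # both agents are shorter than their rest length: residual compression
        for agent in (rod, d):
            span = np.linalg.norm(agent.points[1].position - agent.points[0].position)
            assert span < agent.rest_length + 1e-9 or agent.rest_length == 0.0

    def test_lineage_recorded(self, rng):
        a = make_coccus([0.0, 0.0], mass=300.0)
        d = divide(a, rng)
        assert d.parent_id == a.id


class TestFilamentChain:
    def _filament_rod(self, lib=None):
        rod = make_rod(
            [0, 0, 0], [2, 0, 0], mass=400.0,
            filament=True, **{"division cv": 0.0},
        )
        return rod

    def test_chain_after_n_divisions_is_a_path(self, rng):
        """n divisions produce n+1 connected segments with 180-degree hinges."""
        registry = LinkRegistry()
        segments = [self._filament_rod()]
        n_divisions = 4
        for _ in range(n_divisions):
            # grow then divide the heaviest segment, like the simulation loop
            target = max(segments, key=lambda s: s.mass)
            grow(target, 1.0, 400.0)
            update_geometry(target)
            segments.append(divide(target, rng, registry))
        assert len(segments) == n_divisions + 1
        # link graph over agents is a single path
        import networkx as nx

        g = nx.Graph()
        for s in segments:
            g.add_node(s.id)
        for link in registry.links:
            g.add_edge(link.agent_a, link.agent_b)
        assert nx.is_connected(g)
        assert sorted(d for _, d in g.degree())[-1] <= 2
        assert g.number_of_edges() == len(segments) - 1
        for hinge in registry.hinges:
            assert hinge.rest_angle == pytest.approx(math.pi)

    def test_dropping_agent_removes_its_links(self, rng):
        registry = LinkRegistry()
        rod = self._filament_rod()
        d = divide(rod, rng, registry)
        registry.drop_agent(d.id)
        assert registry.neighbors_of(rod.id) == set()


class TestDifferentiate:
    def _lib(self):
        from microsim.species import SpeciesLibrary

        lib = SpeciesLibrary()
        lib.add_module("base", {"density": 150.0, "isRod": 0.0, "rodSwitchMass": 250.0})
        lib.add_module(
            "rod-form",
            {"morphology": BACILLUS, "isRod": 1.0, "rod radius": 0.4},
        )
        lib.add_species("switcher", ["base"], {
            "differentiation": [
                {"condition": "mass >= rodSwitchMass & isRod = 0", "module": "rod-form"}
            ]
        })
        return lib

    def test_condition_false_leaves_agent(self, rng):
        lib = self._lib()
        a = Agent("switcher", [MassPoint(np.zeros(3), 100.0)], library=lib)
        update_geometry(a)
        assert differentiate(a, {}, rng) is False
        assert a.kind == COCCUS

    def test_coccus_becomes_rod_at_threshold_mass_conserved(self, rng):
        lib = self._lib()
        a = Agent("switcher", [MassPoint(np.zeros(3), 300.0)], library=lib)
        update_geometry(a)
        assert differentiate(a, {}, rng) is True
        assert a.kind == BACILLUS
        assert len(a.points) == 2
        assert a.mass == pytest.approx(300.0)
        # switch happens once: the isRod guard blocks re-triggering
        assert differentiate(a, {}, rng) is False

    def test_switch_to_unknown_module_is_config_error(self, rng):
        lib = self._lib()
        a = Agent(
            "switcher",
            [MassPoint(np.zeros(3), 300.0)],
            aspects={"differentiation": [{"condition": "mass > 0", "module": "nope"}]},
            library=lib,
        )
        update_geometry(a)
        with pytest.raises(KeyError):
            differentiate(a, {}, rng)


class TestDensityScaling2D:
    def test_equal_radius_construction(self):
        # r3d = 1 um sphere: m = rho * 4pi/3; extruded disc of r=1, h=1
        rho = 150.0
        mass = rho * 4 * math.pi / 3
        eff = scale_density_2d(rho, mass, thickness=1.0)
        assert eff == pytest.approx(mass / math.pi)

    def test_identity_at_special_thickness(self):
        """Effective density equals 3D density exactly when h = (4/3) r."""
        rho, mass = 150.0, 400.0
        r3 = radius_from_volume(mass / rho)
        eff = scale_density_2d(rho, mass, thickness=4.0 * r3 / 3.0)
        assert eff == pytest.approx(rho, rel=1e-12)

    def test_packing_correction_factor(self):
        factor = sphere_circle_packing_factor()
        assert factor == pytest.approx(0.82, abs=0.005)
        assert factor == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-12)
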