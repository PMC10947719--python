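"""Spawners, summaries, density grids and SVG rendering."""

import numpy as np
import pytest

from conftest import make_coccus
from microsim.initialization import (
    SpawnerSpec,
    spawn_alternating,
    spawn_distributed,
    spawn_random,
)
from microsim.observe import RenderStyle, agent_table, density_grid, render_svg, summarize
from microsim.spatial import BoundarySpec, SoluteField, SpatialCompartment


class TestSpawners:
    def test_distributed_line_positions(self, library):
        spec = SpawnerSpec("bug", 5, (0.0, 1.0), (100.0, 1.0), interval=20.0,
                           kind="distributed")
        agents = spawn_distributed(spec, library)
        xs = sorted(a.center[0] for a in agents)
        assert xs == pytest.approx([10.0, 30.0, 50.0, 70.0, 90.0])

    def test_distributed_overflow_rejected(self, library):
        spec = SpawnerSpec("bug", 10, (0.0, 0.0), (100.0, 0.0), interval=20.0,
                           kind="distributed")
        with pytest.raises(ValueError):
            spawn_distributed(spec, library)

    def test_random_positions_uniform(self, library, rng):
        """Empirical mean of 10^4 uniform spawns is the region center (3 s.e.)."""
        spec = SpawnerSpec("bug", 10_000, (0.0, 0.0), (10.0, 4.0))
        agents = spawn_random(spec, rng, library)
        pos = np.array([a.center for a in agents])
        assert np.all(pos >= 0.0) and np.all(pos <= [10.0, 4.0])
        se = np.array([10.0, 4.0]) / np.sqrt(12 * len(agents))
        assert np.all(np.abs(pos.mean(axis=0) - [5.0, 2.0]) < 3 * se)

    def test_alternating_species_pattern(self, library):
        library.add_species("other", ["coccoid"])
        agents = spawn_alternating(
            "bug", "other", 10, (0.0, 0.5), (100.0, 0.5), library
        )
        pattern = [a.species for a in sorted(agents, key=lambda a: a.center[0])]
        assert pattern == ["bug", "other"] * 5


def _compartment_with_agents():
    comp = SpatialCompartment(
        "c", (20.0, 20.0), 2.0,
        boundaries={(1, 1): BoundarySpec("dirichlet", {"oxygen": 1e-3})},
    )
    comp.add_solute(SoluteField("oxygen", 7.2e6), initial=1e-3)
    comp.agents = [
        make_coccus([3.0, 3.0], mass=100.0),
        make_coccus([13.0, 3.0], mass=200.0),
        make_coccus([13.0, 13.0], mass=300.0),
    ]
    comp.agents[0].species = "RS"
    comp.agents[1].species = "YS"
    comp.agents[2].species = "YS"
    return comp


class TestSummarize:
    def test_empty_compartment(self):
        comp = SpatialCompartment("c", (10.0, 10.0), 1.0)
        comp.add_solute(SoluteField("s", 1.0), initial=0.25)
        row = summarize(comp, time=3.0)
        assert row["agent_count"] == 0
        assert row["mean_s"] == pytest.approx(0.25)

    def test_species_filter_matches_census(self):
        comp = _compartment_with_agents()
        row = summarize(comp, 0.0, filters={"ys": "species_YS = 1"})
        assert row["count_ys"] == 2
        assert row["mass_ys"] == pytest.approx(500.0)

    def test_disjoint_filters_partition_total(self):
        comp = _compartment_with_agents()
        row = summarize(
            comp, 0.0,
            filters={"a": "species_RS = 1", "b": "species_RS = 0"},
        )
        assert row["count_a"] + row["count_b"] == row["agent_count"]
        assert row["mass_a"] + row["mass_b"] == pytest.approx(row["agent_mass"])

    def test_agent_table_columns(self):
        df = agent_table(_compartment_with_agents().agents)
        assert set(df.columns) >= {"id", "species", "mass", "x0", "x1", "morphology"}
        assert len(df) == 3


class TestDensityGrid:
    def test_single_agent_single_voxel(self):
        grid = density_grid([make_coccus([1.0, 1.0], mass=120.0)], (10.0, 10.0), 2.0)
        assert grid.density[0, 0] == pytest.approx(120.0 / grid.voxel_volume)
        assert np.count_nonzero(grid.density) == 1

    def test_total_mass_conserved(self, rng):
        agents = [
            make_coccus(rng.uniform(0, 10, 2), mass=float(rng.uniform(50, 400)))
            for _ in range(200)
        ]
        grid = density_grid(agents, (10.0, 10.0), 1.0)
        assert grid.total_mass() == pytest.approx(sum(a.mass for a in agents), rel=1e-9)

    def test_matches_histogram_oracle(self, rng):
        """Per-bin masses equal numpy's 2D weighted histogram."""
        agents = [
            make_coccus(rng.uniform(0, 20, 2), mass=float(rng.uniform(50, 400)))
            for _ in range(300)
        ]
        res = 2.0
        grid = density_grid(agents, (20.0, 20.0), res)
        pos = np.array([a.center for a in agents])
        w = np.array([a.mass for a in agents])
        hist, _, _ = np.histogram2d(
            pos[:, 0], pos[:, 1], bins=10, range=[[0, 20], [0, 20]], weights=w
        )
        assert np.allclose(grid.density * grid.voxel_volume, hist)

    def test_species_filter(self):
        comp = _compartment_with_agents()
        grid = density_grid(comp.agents, (20.0, 20.0), 2.0, species_filter="YS")
        assert grid.total_mass() == pytest.approx(500.0)


class TestRender:
    def test_empty_state_valid_document(self):
        comp = SpatialCompartment("c", (10.0, 10.0), 1.0)
        svg = render_svg(comp)
        assert svg.startswith("<?xml")
        assert "<svg" in svg and "</svg>" in svg

    def test_gradient_black_at_max_white_at_zero(self):
        comp = _compartment_with_agents()
        comp.solutes["oxygen"].field[:, :] = 0.0
        comp.solutes["oxygen"].field[0, 0] = 1e-3
        style = RenderStyle(background_solute="oxygen", background_max=1e-3)
        svg = render_svg(comp, style)
        assert 'fill="#000000"' in svg  # the max-concentration cell
        assert 'fill="#ffffff"' in svg  # zero cells

    def test_byte_identical_rerender(self):
        comp = _compartment_with_agents()
        style = RenderStyle(species_colors={"RS": "#2040c0", "YS": "#c03030"})
        assert render_svg(comp, style) == render_svg(comp, style)

    def test_brightness_expression_modulates_color(self):
        comp = _compartment_with_agents()
        style = RenderStyle(
            species_colors={"RS": "#ff0000", "YS": "#ff0000"},
            brightness_expression="mass / 300",
        )
        svg = render_svg(comp, style)
        assert 'fill="#ff0000"' in svg  # the 300 fg agent at full brightness
        assert 'fill="#550000"' in svg  # the 100 fg agent at 1/3 brightness

    def test_rendering_does_not_mutate_state(self):
        comp = _compartment_with_agents()
        before = [(a.mass, a.center.copy()) for a in comp.agents]
        render_svg(comp)
        after = [(a.mass, a.center.copy()) for a in comp.agents]
        for (m0, p0), (m1, p1) in zip(before, after):
            assert m0 == m1 and np.array_equal(p0, p1)
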