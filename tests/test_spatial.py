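"""Pseudo-steady-state reaction-diffusion on the Cartesian grid."""

import math

import numpy as np
import pytest

from conftest import make_coccus
from microsim.reactions import Reaction
from microsim.spatial import BoundarySpec, PdeError, SoluteField, SpatialCompartment

MG_PER_L = 1e-3
OMEGA = 7.2e6


def column(n_cells=50, height=100.0, top=1.0, bottom=None, omega=OMEGA):
    boundaries = {
        (0, 0): BoundarySpec("noflux") if bottom is None else BoundarySpec("dirichlet", {"s": bottom}),
        (0, 1): BoundarySpec("dirichlet", {"s": top}),
    }
    comp = SpatialCompartment("col", (height,), height / n_cells, boundaries=boundaries)
    comp.add_solute(SoluteField("s", omega), initial=top)
    return comp


class TestLinearAndParabolic:
    def test_linear_profile_exact_at_nodes(self):
        comp = column(n_cells=64, top=1.0, bottom=0.0)
        comp.solve_steady_state()
        x = (np.arange(64) + 0.5) * (100.0 / 64)
        assert np.allclose(comp.solutes["s"].field, x / 100.0, atol=1e-12)

    def test_parabolic_profile_closed_form(self):
        from microsim.scenarios.verification import diffusion_parabolic

        result = diffusion_parabolic()
        assert result.rel_dev < 2e-4  # 0.02%

    def test_first_order_consumption_cosh_profile(self):
        """Semi-infinite analogue: S = S_top cosh(x/l)/cosh(L/l), l = sqrt(w/k)."""
        height, n = 200.0, 400
        k = 7.2e2  # 1/h -> penetration depth l = 100 um? no: sqrt(7.2e6/7.2e2) = 100
        comp = column(n_cells=n, height=height, top=1.0)
        comp.add_reaction(Reaction("uptake", {"s": -1.0}, rate="k*s", params={"k": k}))
        comp.solve_steady_state()
        x = (np.arange(n) + 0.5) * (height / n)
        ell = math.sqrt(OMEGA / k)
        exact = np.cosh(x / ell) / math.cosh(height / ell)
        dev = np.max(np.abs(comp.solutes["s"].field - exact)) / exact.max()
        assert dev < 2e-4

    def test_thin_layer_surface_concentration(self):
        from microsim.scenarios.verification import thin_cell_layer

        result = thin_cell_layer()
        assert result.value == pytest.approx(1.8, rel=2e-4)

    def test_thick_layer_linear_in_boundary_layer(self):
        from microsim.scenarios.verification import thick_cell_layer

        result = thick_cell_layer()
        assert result.rel_dev < 1e-3  # departure from linearity, relative to bulk
        assert result.extras["depleted_min"] < 0.05  # mg/L: depleted at depth


class TestSolverContracts:
    def test_matches_dense_direct_solve(self):
        """Converged field equals the dense solve of the same linear system."""
        comp = column(n_cells=40, top=2.0 * MG_PER_L)
        comp.add_reaction(
            Reaction("uptake", {"s": -1.0}, rate="q0", params={"q0": 0.5})
        )
        comp.solve_steady_state()
        A, g, _ = comp._assemble(comp.solutes["s"])
        q = np.full(40, -0.5)
        dense = np.linalg.solve(A.toarray(), -(g + q))
        assert np.allclose(comp.solutes["s"].field, dense, rtol=1e-8, atol=1e-18)

    def test_transient_integration_agrees_with_steady_solver(self):
        """Time-marching Eq of motion to stationarity lands on the same field."""
        steady = column(n_cells=30, top=1.0)
        steady.add_reaction(Reaction("uptake", {"s": -1.0}, rate="k*s", params={"k": 100.0}))
        steady.solve_steady_state()
        transient = column(n_cells=30, top=1.0)
        transient.add_reaction(Reaction("uptake", {"s": -1.0}, rate="k*s", params={"k": 100.0}))
        transient.integrate_transient(t_end=50.0, rtol=1e-10)
        assert np.allclose(
            transient.solutes["s"].field, steady.solutes["s"].field, rtol=1e-5
        )

    def test_closed_box_conserves_total_mass(self):
        """All no-flux, no reactions: repeated solves keep total solute mass."""
        comp = SpatialCompartment("box", (20.0, 20.0), 2.0)
        comp.add_solute(SoluteField("s", OMEGA), initial=0.0)
        comp.solutes["s"].field = np.random.default_rng(0).uniform(0, 1, (10, 10))
        total0 = comp.total_solute_mass("s")
        for _ in range(3):
            comp.solve_steady_state()
        assert comp.total_solute_mass("s") == pytest.approx(total0, rel=1e-9)
        # and the steady state is uniform
        assert np.ptp(comp.solutes["s"].field) < 1e-9

    def test_nonconvergence_is_an_error_not_a_silent_field(self):
        comp = column(n_cells=10, top=1.0)
        comp.add_reaction(Reaction("r", {"s": -1.0}, rate="k*s", params={"k": 1.0}))
        with pytest.raises(PdeError):
            comp.solve_steady_state(max_iter=0)


class TestBiomassMapping:
    def _biofilm(self):
        comp = SpatialCompartment(
            "b",
            (8.0, 8.0),
            2.0,
            boundaries={
                (1, 1): BoundarySpec("dirichlet", {"oxygen": 1.0 * MG_PER_L}),
            },
        )
        comp.add_solute(SoluteField("oxygen", OMEGA), initial=1.0 * MG_PER_L)
        return comp

    def test_one_agent_one_voxel_rate(self):
        comp = self._biofilm()
        rxn = Reaction(
            "uptake", {"oxygen": -1.0}, rate="5.0", catalyst="agent"
        )
        comp.agents.append(make_coccus([1.0, 1.0], reactions=[rxn]))
        q, growth = comp.map_biomass_to_grid()
        assert q["oxygen"][0, 0] == pytest.approx(-5.0 / comp.voxel_volume)
        assert np.count_nonzero(q["oxygen"]) == 1

    def test_half_open_voxel_convention(self):
        comp = self._biofilm()
        rxn = Reaction("uptake", {"oxygen": -1.0}, rate="1.0", catalyst="agent")
        # exactly on an interior face -> upper voxel; on the domain face -> last
        comp.agents.append(make_coccus([2.0, 2.0], reactions=[rxn]))
        comp.agents.append(make_coccus([8.0, 8.0], reactions=[rxn]))
        q, _ = comp.map_biomass_to_grid()
        assert q["oxygen"][1, 1] != 0.0
        assert q["oxygen"][3, 3] != 0.0

    def test_agent_outside_domain_is_hard_error(self):
        comp = self._biofilm()
        comp.agents.append(make_coccus([9.5, 1.0]))
        with pytest.raises(PdeError):
            comp.map_biomass_to_grid()

    def test_grid_consumption_equals_agent_consumption(self, rng):
        """Integrated q over the grid = sum of agent rates (mass balance)."""
        comp = self._biofilm()
        rates = rng.uniform(0.5, 3.0, size=12)
        for k, r in enumerate(rates):
            rxn = Reaction(
                "uptake", {"oxygen": -1.0}, rate="r", catalyst="agent",
                params={"r": float(r)},
            )
            pos = rng.uniform(0.2, 7.8, size=2)
            comp.agents.append(make_coccus(pos, reactions=[rxn]))
        q, _ = comp.map_biomass_to_grid()
        total_grid = q["oxygen"].sum() * comp.voxel_volume
        assert total_grid == pytest.approx(-rates.sum(), rel=1e-9)


class TestBoundaries:
    def test_periodic_pair_required(self):
        with pytest.raises(ValueError):
            SpatialCompartment(
                "bad", (10.0,), 1.0,
                boundaries={(0, 0): BoundarySpec("periodic")},
            )

    def test_periodic_agent_wraparound(self):
        comp = SpatialCompartment(
            "b", (10.0, 10.0), 1.0,
            boundaries={
                (0, 0): BoundarySpec("periodic"),
                (0, 1): BoundarySpec("periodic"),
            },
        )
        a = make_coccus([10.3, 5.0])
        comp.agents.append(a)
        comp.wrap_agents()
        assert a.center[0] == pytest.approx(0.3)

    def test_solid_faces_become_planes(self):
        comp = SpatialCompartment("b", (10.0, 10.0), 1.0)
        planes = comp.surfaces()
        assert len(planes) == 4  # all faces default to no-flux / solid
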