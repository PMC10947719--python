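"""Force models, Newton's third law, relaxation integrators and shoving."""

import math

import numpy as np
import pytest

from conftest import make_coccus, make_rod
from microsim.agents import LinkRegistry
from microsim.forces import (
    FN,
    PA,
    hertz_force,
    hooke_spring,
    terminal_velocity,
    torsion_forces,
    torsion_spring,
)
from microsim.geometry import Domain
from microsim.mechanics import (
    Plane,
    RelaxationConfig,
    UnsupportedMorphologyError,
    relax,
    shove,
)

FREE2 = Domain((50.0, 50.0), (False, False))


class TestForceModels:
    def test_hertz_zero_at_contact(self):
        assert hertz_force(1.0, 1.0, 0.0) == 0.0

    def test_hertz_negative_overlap_gives_zero(self):
        assert hertz_force(1.0, 1.0, -0.5) == 0.0

    def test_hertz_unit_inputs(self):
        assert hertz_force(1.0, 1.0, 1.0) == pytest.approx(4.0 / 3.0)

    def test_hertz_three_halves_scaling(self, rng):
        for _ in range(10):
            r, e, xi = rng.uniform(0.1, 3.0, 3)
            assert hertz_force(r, e, 4 * xi) / hertz_force(r, e, xi) == pytest.approx(8.0)

    def test_hooke_zero_extension(self):
        assert hooke_spring(10.0, 0.0) == 0.0

    def test_torsion_zero_deflection(self):
        assert torsion_spring(1.0, 0.0, 1.0) == 0.0

    def test_torsion_direct_value(self):
        assert torsion_spring(1.0, math.pi / 2, 2.0) == pytest.approx(math.pi / 4)

    def test_torsion_straight_chain_at_rest_is_force_free(self):
        p1, p2, p3 = np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([2.0, 0.0])
        f1, f2, f3 = torsion_forces(p1, p2, p3, kappa=5.0, rest_angle=math.pi)
        assert np.allclose(f1, 0) and np.allclose(f2, 0) and np.allclose(f3, 0)

    def test_torsion_zero_net_force_and_torque(self, rng):
        """Angular spring gradient: net force and net torque vanish."""
        for _ in range(20):
            p1, p2, p3 = rng.uniform(-2, 2, (3, 3))
            f1, f2, f3 = torsion_forces(p1, p2, p3, kappa=3.0, rest_angle=math.pi)
            assert np.allclose(f1 + f2 + f3, 0, atol=1e-9)
            torque = np.cross(p1 - p2, f1) + np.cross(p3 - p2, f3)
            assert np.allclose(torque, 0, atol=1e-9)

    def test_torsion_magnitude_matches_angular_hooke(self):
        # right angle with unit arms: |F| on each end = kappa * (pi/2) / L
        p1, p2, p3 = np.array([1.0, 0.0]), np.array([0.0, 0.0]), np.array([0.0, 2.0])
        f1, _, f3 = torsion_forces(p1, p2, p3, kappa=2.0, rest_angle=math.pi)
        assert np.linalg.norm(f1) == pytest.approx(2.0 * (math.pi / 2) / 1.0)
        assert np.linalg.norm(f3) == pytest.approx(2.0 * (math.pi / 2) / 2.0)

    def test_terminal_velocity_zero_and_linear(self):
        assert np.allclose(terminal_velocity(np.zeros(3), 1.0, 1.0), 0)
        f = np.array([2.0, 0.0, 1.0])
        v1 = terminal_velocity(f, 1.0, 1.0)
        v2 = terminal_velocity(2 * f, 1.0, 1.0)
        assert np.allclose(v2, 2 * v1)

    def test_terminal_velocity_unit_construction(self):
        v = terminal_velocity(np.array([1.0, 0.0]), 1.0, 1.0 / (6 * math.pi))
        assert np.linalg.norm(v) == pytest.approx(1.0)


class TestNewtonThirdLaw:
    def test_internal_forces_sum_to_zero(self, rng):
        """Total momentum change from internal forces vanishes per sweep."""
        from microsim.mechanics import _MechState

        domain = Domain((20.0, 20.0), (True, False))
        agents = []
        for _ in range(30):
            agents.append(make_coccus(rng.uniform(2, 18, 2), mass=400.0))
        for _ in range(5):
            p = rng.uniform(2, 16, 2)
            agents.append(make_rod(p, p + [1.5, 0.3], mass=500.0))
        registry = LinkRegistry()
        state = _MechState(agents, domain, registry, RelaxationConfig())
        F, _ = state.forces(state.pos, planes=[])  # no walls: internal only
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-6 * max(np.abs(F).max(), 1))


class TestRelaxation:
    def test_isolated_agent_converges_immediately(self):
        a = make_coccus([10.0, 10.0])
        result = relax([a], RelaxationConfig(), FREE2)
        assert result.converged
        assert result.iterations == 1
        assert result.residual_force == 0.0

    def test_two_overlapping_spheres_separate_symmetrically(self):
        a = make_coccus([10.0, 10.0], mass=300.0)
        b = make_coccus([10.0 + 2 * a.radius - 0.5, 10.0], mass=300.0)
        mid0 = 0.5 * (a.center + b.center)
        result = relax([a, b], RelaxationConfig(force_tolerance=1.0 * FN), FREE2)
        assert result.converged
        gap = np.linalg.norm(a.center - b.center) - 2 * a.radius
        assert gap >= -RelaxationConfig().max_overlap
        mid1 = 0.5 * (a.center + b.center)
        assert np.allclose(mid0, mid1, atol=1e-6)  # symmetric displacement

    def _two_body_final_overlap(self, integrator, h, t_end=2e-9):
        """Integrate the two-sphere Hertz relaxation with a fixed step."""
        a = make_coccus([10.0, 10.0], mass=300.0)
        b = make_coccus([10.0 + 2 * a.radius - 0.4, 10.0], mass=300.0)
        steps = int(round(t_end / h))
        config = RelaxationConfig(
            integrator=integrator,
            max_step=h,
            max_displacement=None,
            stability_cap=False,
            max_iterations=steps,
            force_tolerance=0.0,
        )
        relax([a, b], config, FREE2)
        return 2 * a.radius - np.linalg.norm(a.center - b.center)

    @staticmethod
    def _two_body_exact(xi0, r, e_pa, t):
        """Closed form: dxi/dt = -c xi^(3/2) => xi(t) = xi0 (1 + c sqrt(xi0) t / 2)^-2."""
        from microsim.forces import PA_S

        r_eff = r / 2.0
        e_eff = e_pa / 2.0
        drag = 6 * math.pi * r * 1e-3 * PA_S
        c = 2.0 * (4.0 / 3.0) * r_eff * e_eff / drag
        return xi0 * (1.0 + 0.5 * c * math.sqrt(xi0) * t) ** -2

    def test_integrator_orders_on_two_body_relaxation(self):
        """Euler error ~ O(h), Heun error ~ O(h^2) against the closed form."""
        a = make_coccus([0.0, 0.0], mass=300.0)
        r = a.radius
        t_end = 2e-9
        exact = self._two_body_exact(0.4, r, 1e5 * PA, t_end)
        errors = {}
        for integrator in ("euler", "heun"):
            errs = []
            for h in (t_end / 25, t_end / 50, t_end / 100):
                xi = self._two_body_final_overlap(integrator, h, t_end)
                errs.append(abs(xi - exact))
            errors[integrator] = errs
        # halving h should halve Euler's error and quarter Heun's
        e = errors["euler"]
        assert e[0] / e[1] == pytest.approx(2.0, rel=0.35)
        assert e[1] / e[2] == pytest.approx(2.0, rel=0.35)
        hn = errors["heun"]
        assert hn[0] / hn[1] == pytest.approx(4.0, rel=0.5)
        assert hn[1] / hn[2] == pytest.approx(4.0, rel=0.5)
        assert hn[2] < e[2]

    def test_overcompressed_cluster_force_decays(self, rng):
        """Max interaction force decays monotonically (allowing plateaus)."""
        from microsim.scenarios.verification import relaxation_convergence

        report = relaxation_convergence(n_agents=12, chunks=60)
        series = report["residual_series_fn"]
        assert report["converged"]
        # sampled every few sweeps: require overall decay and near-monotonicity
        drops = sum(1 for x, y in zip(series, series[1:]) if y <= x * 1.05)
        assert drops >= 0.9 * (len(series) - 1)
        assert series[-1] < 1e-3 * series[0]

    def test_boundary_plane_pushes_agent_inside(self):
        a = make_coccus([0.2, 10.0], mass=300.0)  # stuck in the x=0 wall
        result = relax([a], RelaxationConfig(), FREE2, surfaces=[Plane((1, 0), 0.0)])
        assert result.converged
        assert a.center[0] >= a.radius - 1e-3

    def test_periodic_translation_invariance(self, rng):
        """Wrapping the whole configuration by a lattice vector is a no-op."""
        domain = Domain((20.0, 20.0), (True, True))
        agents_a = [make_coccus(rng.uniform(0, 20, 2), mass=300.0) for _ in range(12)]
        agents_b = [make_coccus(a.center + [20.0, 40.0], mass=300.0) for a in agents_a]
        config = RelaxationConfig(max_iterations=60)
        relax(agents_a, config, domain)
        relax(agents_b, config, domain)
        for a, b in zip(agents_a, agents_b):
            assert np.allclose(a.center, b.center, atol=1e-9)


class TestShove:
    def test_no_overlap_is_noop(self):
        a = make_coccus([5.0, 5.0])
        b = make_coccus([15.0, 5.0])
        p0 = (a.center.copy(), b.center.copy())
        result = shove([a, b], FREE2)
        assert result.converged
        assert np.allclose(a.center, p0[0]) and np.allclose(b.center, p0[1])

    def test_two_spheres_pushed_to_exact_contact(self):
        a = make_coccus([10.0, 10.0], mass=300.0)
        b = make_coccus([10.0 + a.radius, 10.0], mass=300.0)
        shove([a, b], FREE2, shoving_factor=1.0, tolerance=1e-9)
        dist = np.linalg.norm(a.center - b.center)
        assert dist == pytest.approx(2 * a.radius, abs=1e-6)
        # pushed apart symmetrically
        assert a.center[1] == b.center[1]

    def test_rejects_rods(self):
        rod = make_rod([5, 5], [7, 5])
        with pytest.raises(UnsupportedMorphologyError):
            shove([rod], FREE2)

    def test_random_packing_terminates_without_overlap(self, rng):
        # 200 agents over a domain large enough that a packing exists
        domain = Domain((40.0, 40.0), (True, True))
        agents = [make_coccus(rng.uniform(0, 40, 2), mass=300.0) for _ in range(200)]
        result = shove(agents, domain, tolerance=1e-4, max_iterations=5000)
        assert result.converged
        assert result.max_overlap <= 1.1e-4
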