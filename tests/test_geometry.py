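"""Collision detection: gaps, witness points, periodic minimum image.

Includes the exhaustive 36-scenario matrix (sphere, rod, plane, voxel
pairs in hit / miss / periodic-hit / periodic-miss configurations) and
randomized oracles (brute force over periodic image shifts; dense
sampling along segments).
"""

import itertools

import numpy as np
import pytest

from microsim.geometry import (
    CollisionResult,
    Domain,
    closest_points_segments,
    distance_rod_plane,
    distance_rod_rod,
    distance_rod_voxel,
    distance_sphere_plane,
    distance_sphere_rod,
    distance_sphere_sphere,
    distance_sphere_voxel,
)

BOX = Domain((10.0, 10.0, 10.0), (True, True, True))
FREE = Domain((10.0, 10.0, 10.0), (False, False, False))


def a3(*xs):
    return np.array(xs, dtype=float)


class TestSphereSphere:
    def test_simple_gap(self):
        res = distance_sphere_sphere(a3(0, 0, 0), 1.0, a3(3, 0, 0), 1.0, FREE)
        assert res.gap == pytest.approx(1.0)
        assert res.normal @ a3(-1, 0, 0) == pytest.approx(1.0)

    def test_overlap_negative_gap(self):
        res = distance_sphere_sphere(a3(0, 0, 0), 1.0, a3(1.5, 0, 0), 1.0, FREE)
        assert res.gap == pytest.approx(-0.5)
        assert res.overlap == pytest.approx(0.5)

    def test_periodic_wrap(self):
        res = distance_sphere_sphere(a3(0.5, 5, 5), 0.4, a3(9.5, 5, 5), 0.4, BOX)
        assert res.gap == pytest.approx(0.2)

    def test_coincident_centers_deterministic_normal(self):
        res = distance_sphere_sphere(a3(1, 1, 1), 0.5, a3(1, 1, 1), 0.7, FREE)
        assert res.gap == pytest.approx(-1.2)
        assert res.normal.tolist() == [1.0, 0.0, 0.0]

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            pa, pb = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
            ra, rb = rng.uniform(0.2, 1.5, 2)
            r1 = distance_sphere_sphere(pa, ra, pb, rb, BOX)
            r2 = distance_sphere_sphere(pb, rb, pa, ra, BOX)
            assert r1.gap == pytest.approx(r2.gap, abs=1e-12)
            assert np.allclose(r1.normal, -r2.normal)

    def test_periodic_brute_force_oracle(self, rng):
        """Gap equals the minimum over all 27 lattice image shifts."""
        for _ in range(50):
            pa, pb = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
            ra, rb = rng.uniform(0.2, 1.0, 2)
            res = distance_sphere_sphere(pa, ra, pb, rb, BOX)
            best = min(
                np.linalg.norm(pa - (pb + 10.0 * np.array(shift))) - ra - rb
                for shift in itertools.product((-1, 0, 1), repeat=3)
            )
            assert res.gap == pytest.approx(best, abs=1e-10)


class TestSphereRod:
    def test_perpendicular_bisector(self):
        res = distance_sphere_rod(a3(1, 3, 0), 0.5, a3(0, 0, 0), a3(2, 0, 0), 0.4, FREE)
        assert res.gap == pytest.approx(3.0 - 0.9)

    def test_beyond_endpoint_uses_endpoint(self):
        res = distance_sphere_rod(a3(5, 0, 0), 0.5, a3(0, 0, 0), a3(2, 0, 0), 0.4, FREE)
        assert res.gap == pytest.approx(3.0 - 0.9)


class TestRodRod:
    def test_collinear_disjoint_uses_endpoints(self):
        res = distance_rod_rod(
            a3(0, 0, 0), a3(1, 0, 0), 0.2, a3(3, 0, 0), a3(4, 0, 0), 0.2, FREE
        )
        assert res.gap == pytest.approx(2.0 - 0.4)

    def test_crossing_perpendicular(self):
        res = distance_rod_rod(
            a3(-1, 0, 0), a3(1, 0, 0), 0.3, a3(0, -1, 1), a3(0, 1, 1), 0.3, FREE
        )
        assert res.gap == pytest.approx(1.0 - 0.6)

    def test_random_pairs_against_dense_sampling(self, rng):
        """Core distance matches brute-force sampling of both segments."""
        ts = np.linspace(0.0, 1.0, 400)
        for _ in range(60):
            p1, q1, p2, q2 = (rng.uniform(0, 5, 3) for _ in range(4))
            s, t = closest_points_segments(p1, q1, p2, q2)
            d_exact = np.linalg.norm((p1 + s * (q1 - p1)) - (p2 + t * (q2 - p2)))
            pa = p1[None, :] + ts[:, None] * (q1 - p1)[None, :]
            pb = p2[None, :] + ts[:, None] * (q2 - p2)[None, :]
            d_brute = np.min(
                np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            )
            assert d_exact <= d_brute + 1e-9
            assert d_exact == pytest.approx(d_brute, abs=5e-3)


class TestCollisionMatrix:
    """The exhaustive hit/miss matrix over object pairs.

    36 configurations: sphere-sphere, sphere-rod, rod-rod (hit, miss,
    periodic hit, periodic miss), sphere-plane, rod-plane (hit, miss),
    sphere-voxel, rod-voxel (hit, miss, periodic hit, periodic miss),
    plus grazing sphere-sphere and crossing rod-rod checks.
    """

    CASES = []
    # sphere-sphere
    CASES += [
        ("ss-hit", lambda: distance_sphere_sphere(a3(5, 5, 5), 1, a3(6.5, 5, 5), 1, BOX), True),
        ("ss-miss", lambda: distance_sphere_sphere(a3(2, 2, 2), 1, a3(6, 2, 2), 1, BOX), False),
        ("ss-per-hit", lambda: distance_sphere_sphere(a3(0.4, 5, 5), 1, a3(9.6, 5, 5), 1, BOX), True),
        ("ss-per-miss", lambda: distance_sphere_sphere(a3(1.5, 5, 5), 1, a3(8.5, 5, 5), 1, BOX), False),
        ("ss-graze-hit", lambda: distance_sphere_sphere(a3(5, 5, 5), 1, a3(6.9, 5, 5), 1, BOX), True),
        ("ss-graze-miss", lambda: distance_sphere_sphere(a3(5, 5, 5), 1, a3(7.1, 5, 5), 1, BOX), False),
        ("ss-diag-per-hit", lambda: distance_sphere_sphere(a3(0.5, 0.5, 5), 1, a3(9.5, 9.5, 5), 1, BOX), True),
        ("ss-diag-per-miss", lambda: distance_sphere_sphere(a3(1.6, 1.6, 5), 1, a3(8.4, 8.4, 5), 1, BOX), False),
    ]
    # sphere-rod
    CASES += [
        ("sr-hit", lambda: distance_sphere_rod(a3(5, 6, 5), 0.8, a3(4, 5, 5), a3(6, 5, 5), 0.4, BOX), True),
        ("sr-miss", lambda: distance_sphere_rod(a3(5, 8, 5), 0.8, a3(4, 5, 5), a3(6, 5, 5), 0.4, BOX), False),
        ("sr-per-hit", lambda: distance_sphere_rod(a3(0.5, 5, 5), 0.8, a3(9.0, 5, 5), a3(9.7, 5, 5), 0.4, BOX), True),
        ("sr-per-miss", lambda: distance_sphere_rod(a3(2.0, 5, 5), 0.8, a3(8.5, 5, 5), a3(9.5, 5, 5), 0.4, BOX), False),
        ("sr-end-hit", lambda: distance_sphere_rod(a3(7, 5, 5), 0.8, a3(4, 5, 5), a3(6.5, 5, 5), 0.4, BOX), True),
        ("sr-end-miss", lambda: distance_sphere_rod(a3(8, 5, 5), 0.8, a3(4, 5, 5), a3(6.5, 5, 5), 0.4, BOX), False),
    ]
    # rod-rod
    CASES += [
        ("rr-hit", lambda: distance_rod_rod(a3(4, 5, 5), a3(6, 5, 5), 0.4, a3(5, 4.5, 5), a3(5, 6, 5), 0.4, BOX), True),
        ("rr-miss", lambda: distance_rod_rod(a3(4, 5, 5), a3(6, 5, 5), 0.4, a3(5, 7, 5), a3(5, 9, 5), 0.4, BOX), False),
        ("rr-per-hit", lambda: distance_rod_rod(a3(0.2, 5, 5), a3(1, 5, 5), 0.4, a3(9, 5, 5), a3(9.9, 5, 5), 0.4, BOX), True),
        ("rr-per-miss", lambda: distance_rod_rod(a3(1.5, 5, 5), a3(2.5, 5, 5), 0.4, a3(8, 5, 5), a3(9, 5, 5), 0.4, BOX), False),
        ("rr-cross-hit", lambda: distance_rod_rod(a3(4, 4, 5), a3(6, 6, 5), 0.4, a3(4, 6, 5.5), a3(6, 4, 5.5), 0.4, BOX), True),
        ("rr-cross-miss", lambda: distance_rod_rod(a3(4, 4, 5), a3(6, 6, 5), 0.4, a3(4, 6, 7), a3(6, 4, 7), 0.4, BOX), False),
    ]
    # plane (solid boundary at x = 0, inward normal +x)
    CASES += [
        ("sp-hit", lambda: distance_sphere_plane(a3(0.5, 5, 5), 1.0, a3(1, 0, 0), 0.0), True),
        ("sp-miss", lambda: distance_sphere_plane(a3(2, 5, 5), 1.0, a3(1, 0, 0), 0.0), False),
        ("rp-hit", lambda: distance_rod_plane(a3(0.5, 4, 5), a3(2, 6, 5), 0.6, a3(1, 0, 0), 0.0), True),
        ("rp-miss", lambda: distance_rod_plane(a3(1, 4, 5), a3(2, 6, 5), 0.6, a3(1, 0, 0), 0.0), False),
        ("sp-tilt-hit", lambda: distance_sphere_plane(a3(1, 1, 5), 1.5, a3(1, 1, 0) / np.sqrt(2), 0.0), True),
        ("sp-tilt-miss", lambda: distance_sphere_plane(a3(2, 2, 5), 1.5, a3(1, 1, 0) / np.sqrt(2), 0.0), False),
    ]
    # voxel (axis-aligned cube [4,6]^3)
    V_LO, V_HI = a3(4, 4, 4), a3(6, 6, 6)
    CASES += [
        ("sv-hit", lambda: distance_sphere_voxel(a3(3.5, 5, 5), 0.8, TestCollisionMatrix.V_LO, TestCollisionMatrix.V_HI, BOX), True),
        ("sv-miss", lambda: distance_sphere_voxel(a3(2, 5, 5), 0.8, TestCollisionMatrix.V_LO, TestCollisionMatrix.V_HI, BOX), False),
        ("sv-corner-hit", lambda: distance_sphere_voxel(a3(3.6, 3.6, 3.6), 0.8, TestCollisionMatrix.V_LO, TestCollisionMatrix.V_HI, BOX), True),
        ("sv-corner-miss", lambda: distance_sphere_voxel(a3(3, 3, 3), 0.8, TestCollisionMatrix.V_LO, TestCollisionMatrix.V_HI, BOX), False),
        ("sv-per-hit", lambda: distance_sphere_voxel(a3(0.5, 5, 5), 0.8, a3(9, 4, 4), a3(10, 6, 6), BOX), True),
        ("sv-per-miss", lambda: distance_sphere_voxel(a3(2, 5, 5), 0.8, a3(9, 4, 4), a3(10, 6, 6), BOX), False),
        ("rv-hit", lambda: distance_rod_voxel(a3(3, 5, 5), a3(3.8, 5, 5), 0.5, TestCollisionMatrix.V_LO, TestCollisionMatrix.V_HI, BOX), True),
        ("rv-miss", lambda: distance_rod_voxel(a3(2, 5, 5), a3(3, 5, 5), 0.5, TestCollisionMatrix.V_LO, TestCollisionMatrix.V_HI, BOX), False),
        ("rv-per-hit", lambda: distance_rod_voxel(a3(0.3, 5, 5), a3(1, 5, 5), 0.5, a3(9.2, 4, 4), a3(10, 6, 6), BOX), True),
        ("rv-per-miss", lambda: distance_rod_voxel(a3(1.5, 5, 5), a3(2.5, 5, 5), 0.5, a3(9.2, 4, 4), a3(10, 6, 6), BOX), False),
    ]

    def test_matrix_has_at_least_36_scenarios(self):
        assert len(self.CASES) >= 36

    @pytest.mark.parametrize("name,fn,expect_hit", CASES, ids=[c[0] for c in CASES])
    def test_scenario(self, name, fn, expect_hit):
        res = fn()
        assert (res.gap < 0) == expect_hit


class TestTranslationInvariance:
    def test_lattice_shift_leaves_gaps_unchanged(self, rng):
        """Shifting all positions by a lattice vector changes nothing."""
        shift = np.array([10.0, -10.0, 20.0])
        for _ in range(25):
            pa, pb = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
            ra, rb = rng.uniform(0.2, 1.0, 2)
            r0 = distance_sphere_sphere(pa, ra, pb, rb, BOX)
            r1 = distance_sphere_sphere(pa + shift, ra, pb + shift, rb, BOX)
            assert r0.gap == pytest.approx(r1.gap, abs=1e-10)
            assert np.allclose(r0.normal, r1.normal, atol=1e-10)
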