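"""Collision geometry for sphere-swept bodies.

Agents are spheres (cocci), sphere-swept line segments / capsules
(bacilli, filament segments), and interact with infinite planes (solid
boundaries) and axis-aligned voxels.  The signed gap between two bodies
is the surface-to-surface distance; a negative gap means overlap.  All
distances respect the minimum-image convention on periodic dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Domain",
    "CollisionResult",
    "distance_sphere_sphere",
    "distance_sphere_rod",
    "distance_rod_rod",
    "distance_sphere_plane",
    "distance_rod_plane",
    "distance_sphere_voxel",
    "distance_rod_voxel",
    "closest_point_segment",
    "closest_points_segments",
]

_TIE_NORMAL_AXIS = 0  # deterministic +x normal for coincident geometry


@dataclass(frozen=True)
class Domain:
    """Axis-aligned computational domain with per-dimension periodicity."""

    lengths: tuple[float, ...]
    periodic: tuple[bool, ...]

    def __post_init__(self):
        if len(self.lengths) != len(self.periodic):
            raise ValueError("lengths and periodic flags must have equal length")

    @property
    def dim(self) -> int:
        return len(self.lengths)

    def minimum_image(self, delta: np.ndarray) -> np.ndarray:
        """Wrap a displacement vector to its minimum image."""
        delta = np.array(delta, dtype=float)
        for ax, (L, per) in enumerate(zip(self.lengths, self.periodic)):
            if per:
                delta[..., ax] -= L * np.round(delta[..., ax] / L)
        return delta

    def wrap_position(self, pos: np.ndarray) -> np.ndarray:
        pos = np.array(pos, dtype=float)
        for ax, (L, per) in enumerate(zip(self.lengths, self.periodic)):
            if per:
                pos[..., ax] = np.mod(pos[..., ax], L)
        return pos

    def image_shift(self, from_point: np.ndarray, to_point: np.ndarray) -> np.ndarray:
        """Lattice translation moving ``to_point`` to its image closest to ``from_point``."""
        shift = np.zeros(self.dim)
        delta = np.asarray(to_point, dtype=float) - np.asarray(from_point, dtype=float)
        for ax, (L, per) in enumerate(zip(self.lengths, self.periodic)):
            if per:
                shift[ax] = -L * np.round(delta[ax] / L)
        return shift


def free_domain(dim: int) -> Domain:
    return Domain(tuple([np.inf] * dim), tuple([False] * dim))


@dataclass(frozen=True)
class CollisionResult:
    """Signed gap, contact normal and witness points of a body pair.

    ``gap`` < 0 means the bodies overlap by ``-gap``.  ``normal`` points
    from body b towards body a; swapping the arguments negates it.
    """

    gap: float
    normal: np.ndarray
    point_a: np.ndarray
    point_b: np.ndarray

    @property
    def overlap(self) -> float:
        return max(0.0, -self.gap)

    def swapped(self) -> "CollisionResult":
        return CollisionResult(self.gap, -self.normal, self.point_b, self.point_a)


def _tie_normal(dim: int) -> np.ndarray:
    n = np.zeros(dim)
    n[_TIE_NORMAL_AXIS] = 1.0
    return n


def _result_from_points(pa, pb, ra, rb, dim) -> CollisionResult:
    d = pa - pb
    dist = float(np.linalg.norm(d))
    if dist < 1e-14:
        normal = _tie_normal(dim)
    else:
        normal = d / dist
    gap = dist - ra - rb
    return CollisionResult(
        gap=gap,
        normal=normal,
        point_a=pa - normal * ra,
        point_b=pb + normal * rb,
    )


def distance_sphere_sphere(
    center_a: np.ndarray,
    radius_a: float,
    center_b: np.ndarray,
    radius_b: float,
    domain: Domain | None = None,
) -> CollisionResult:
    if radius_a <= 0 or radius_b <= 0:
        raise ValueError("radii must be positive")
    pa = np.asarray(center_a, dtype=float)
    pb = np.asarray(center_b, dtype=float)
    if domain is not None:
        pb = pb + domain.image_shift(pa, pb)
    return _result_from_points(pa, pb, radius_a, radius_b, len(pa))


def closest_point_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Parameter t in [0, 1] of the point on segment ab closest to p."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-28:
        return 0.0
    return float(np.clip((p - a) @ ab / denom, 0.0, 1.0))


def closest_points_segments(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> tuple[float, float]:
    """Clamped closest-point parameters (s, t) of two segments.

    Standard robust segment-segment algorithm; parallel overlapping
    segments get a deterministic tie-break (smallest valid s).
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-24
    if a <= eps and e <= eps:
        return 0.0, 0.0
    if a <= eps:
        return 0.0, float(np.clip(f / e, 0.0, 1.0))
    c = float(d1 @ r)
    if e <= eps:
        return float(np.clip(-c / a, 0.0, 1.0)), 0.0
    b = float(d1 @ d2)
    denom = a * e - b * b
    if denom > eps * max(a, e) ** 2:
        s = float(np.clip((b * f - c * e) / denom, 0.0, 1.0))
    else:
        s = 0.0  # parallel: deterministic tie-break
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = float(np.clip(-c / a, 0.0, 1.0))
    elif t > 1.0:
        t = 1.0
        s = float(np.clip((b - c) / a, 0.0, 1.0))
    return s, t


def distance_sphere_rod(
    center: np.ndarray,
    radius: float,
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    rod_radius: float,
    domain: Domain | None = None,
) -> CollisionResult:
    p = np.asarray(center, dtype=float)
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    if domain is not None:
        mid = 0.5 * (a + b)
        shift = domain.image_shift(p, mid)
        a = a + shift
        b = b + shift
    t = closest_point_segment(p, a, b)
    foot = a + t * (b - a)
    return _result_from_points(p, foot, radius, rod_radius, len(p))


def distance_rod_rod(
    a1: np.ndarray,
    b1: np.ndarray,
    radius_1: float,
    a2: np.ndarray,
    b2: np.ndarray,
    radius_2: float,
    domain: Domain | None = None,
) -> CollisionResult:
    a1 = np.asarray(a1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if domain is not None:
        shift = domain.image_shift(0.5 * (a1 + b1), 0.5 * (a2 + b2))
        a2 = a2 + shift
        b2 = b2 + shift
    s, t = closest_points_segments(a1, b1, a2, b2)
    pa = a1 + s * (b1 - a1)
    pb = a2 + t * (b2 - a2)
    res = _result_from_points(pa, pb, radius_1, radius_2, len(a1))
    return res


def distance_sphere_plane(
    center: np.ndarray, radius: float, normal: np.ndarray, offset: float
) -> CollisionResult:
    """Gap to the plane {x : n.x = offset}; n is the outward (into-domain) unit normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    p = np.asarray(center, dtype=float)
    signed = float(n @ p) - offset
    gap = signed - radius
    foot = p - signed * n
    return CollisionResult(gap=gap, normal=n, point_a=p - n * radius, point_b=foot)


def distance_rod_plane(
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    radius: float,
    normal: np.ndarray,
    offset: float,
) -> CollisionResult:
    ra = distance_sphere_plane(seg_a, radius, normal, offset)
    rb = distance_sphere_plane(seg_b, radius, normal, offset)
    return ra if ra.gap <= rb.gap else rb


def _closest_point_aabb(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.clip(p, lo, hi)


def distance_sphere_voxel(
    center: np.ndarray,
    radius: float,
    voxel_lo: np.ndarray,
    voxel_hi: np.ndarray,
    domain: Domain | None = None,
) -> CollisionResult:
    p = np.asarray(center, dtype=float)
    lo = np.asarray(voxel_lo, dtype=float)
    hi = np.asarray(voxel_hi, dtype=float)
    if domain is not None:
        shift = domain.image_shift(p, 0.5 * (lo + hi))
        lo = lo + shift
        hi = hi + shift
    q = _closest_point_aabb(p, lo, hi)
    if np.all(q == p):  # center inside box: penetration to the nearest face
        face_gaps = np.minimum(p - lo, hi - p)
        ax = int(np.argmin(face_gaps))
        sign = 1.0 if (p[ax] - lo[ax]) > (hi[ax] - p[ax]) else -1.0
        normal = np.zeros(len(p))
        normal[ax] = sign
        depth = float(face_gaps[ax])
        gap = -(depth + radius)
        foot = p.copy()
        foot[ax] = hi[ax] if sign > 0 else lo[ax]
        return CollisionResult(gap=gap, normal=normal, point_a=p - normal * radius, point_b=foot)
    return _result_from_points(p, q, radius, 0.0, len(p))


def distance_rod_voxel(
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    radius: float,
    voxel_lo: np.ndarray,
    voxel_hi: np.ndarray,
    domain: Domain | None = None,
    tol: float = 1e-10,
) -> CollisionResult:
    """Capsule-voxel gap via ternary search along the segment.

    The point-to-box distance is convex along the segment, so a ternary
    search converges to the global minimum deterministically.
    """
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    lo = np.asarray(voxel_lo, dtype=float)
    hi = np.asarray(voxel_hi, dtype=float)
    if domain is not None:
        shift = domain.image_shift(0.5 * (a + b), 0.5 * (lo + hi))
        lo = lo + shift
        hi = hi + shift

    def dist_at(t: float) -> float:
        p = a + t * (b - a)
        return float(np.linalg.norm(p - _closest_point_aabb(p, lo, hi)))

    t_lo, t_hi = 0.0, 1.0
    while t_hi - t_lo > tol:
        m1 = t_lo + (t_hi - t_lo) / 3.0
        m2 = t_hi - (t_hi - t_lo) / 3.0
        if dist_at(m1) <= dist_at(m2):
            t_hi = m2
        else:
            t_lo = m1
    t = 0.5 * (t_lo + t_hi)
    p = a + t * (b - a)
    return distance_sphere_voxel(p, radius, lo, hi, domain=None)
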