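"""Force-based mechanical relaxation and the legacy shoving alternative.

Between growth steps, agent positions are relaxed to mechanical
equilibrium: pairwise Hertzian contact forces, internal spine springs of
rods, connection springs and torsion hinges of filaments, and repulsion
from solid boundary planes are accumulated synchronously, each
mass-point moves at its Stokes terminal velocity, and positions are
integrated (forward Euler or Heun) until the largest residual force per
point drops below tolerance.

The force sweep is vectorized over flat point/body arrays; candidate
pairs come from a uniform cell list rebuilt each sweep (the
:mod:`~microsim.neighbors` tree serves the generic neighbor-query API
and the oracle tests).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .agents import Agent, BACILLUS, COCCUS, LinkRegistry
from .forces import FN, PA, PA_S, terminal_velocity, torsion_forces
from .geometry import (
    CollisionResult,
    Domain,
    distance_rod_rod,
    distance_sphere_rod,
    distance_sphere_sphere,
)

__all__ = [
    "RelaxationConfig",
    "RelaxResult",
    "Plane",
    "relax",
    "shove",
    "body_gap",
    "UnsupportedMorphologyError",
]

DEFAULT_E = 1e5 * PA  # effective Young's modulus of the cell envelope
DEFAULT_VISCOSITY = 1e-3 * PA_S  # water


class UnsupportedMorphologyError(TypeError):
    pass


@dataclass(frozen=True)
class Plane:
    """Solid boundary plane {x : n.x = offset}, n pointing into the domain."""

    normal: tuple[float, ...]
    offset: float


@dataclass
class RelaxationConfig:
    integrator: str = "euler"  # 'euler' | 'heun'
    max_step: float = 1e-6  # h, cap on the internal pseudo-time step
    force_tolerance: float = 50.0 * FN  # residual net force per point
    max_overlap: float = 0.05  # um, reported diagnostic target
    viscosity: float = DEFAULT_VISCOSITY
    max_iterations: int = 1000
    max_displacement: float | None = 0.1  # um per internal step; None = fixed step
    stiffness: float = 1e5 * PA  # default E_eff source for agents without aspect
    stability_cap: bool = True  # cap dt at the explicit-integration stability limit


@dataclass
class RelaxResult:
    iterations: int
    residual_force: float  # base units
    max_overlap: float
    converged: bool

    @property
    def residual_force_fn(self) -> float:
        return self.residual_force / FN


def body_gap(agent_a: Agent, agent_b: Agent, domain: Domain | None) -> CollisionResult:
    """Exact signed gap between the swept volumes of two agents."""
    a_rod = agent_a.kind == BACILLUS
    b_rod = agent_b.kind == BACILLUS
    if not a_rod and not b_rod:
        return distance_sphere_sphere(
            agent_a.points[0].position,
            agent_a.radius,
            agent_b.points[0].position,
            agent_b.radius,
            domain,
        )
    if not a_rod and b_rod:
        return distance_sphere_rod(
            agent_a.points[0].position,
            agent_a.radius,
            agent_b.points[0].position,
            agent_b.points[1].position,
            agent_b.radius,
            domain,
        )
    if a_rod and not b_rod:
        return distance_sphere_rod(
            agent_b.points[0].position,
            agent_b.radius,
            agent_a.points[0].position,
            agent_a.points[1].position,
            agent_a.radius,
            domain,
        ).swapped()
    return distance_rod_rod(
        agent_a.points[0].position,
        agent_a.points[1].position,
        agent_a.radius,
        agent_b.points[0].position,
        agent_b.points[1].position,
        agent_b.radius,
        domain,
    )


# ---------------------------------------------------------------------------
# flat mechanical state
# ---------------------------------------------------------------------------


class _MechState:
    def __init__(
        self,
        agents: list[Agent],
        domain: Domain,
        registry: LinkRegistry | None,
        config: RelaxationConfig,
    ):
        self.domain = domain
        self.dim = domain.dim
        self.agents = agents
        point_map: dict[tuple[int, int], int] = {}
        pos = []
        prad = []  # collision/drag radius per point (owning body's radius)
        body_first = []
        body_second = []
        body_rad = []
        body_E = []
        spring_i: list[int] = []
        spring_j: list[int] = []
        spring_rest: list[float] = []
        spring_k: list[float] = []
        for bi, agent in enumerate(agents):
            idxs = []
            for pi, p in enumerate(agent.points):
                point_map[(agent.id, pi)] = len(pos)
                idxs.append(len(pos))
                pos.append(np.asarray(p.position, dtype=float))
                prad.append(agent.radius)
            body_first.append(idxs[0])
            body_second.append(idxs[-1])
            body_rad.append(agent.radius)
            body_E.append(float(agent.get("youngs modulus", config.stiffness)))
            if agent.kind == BACILLUS:
                spring_i.append(idxs[0])
                spring_j.append(idxs[1])
                spring_rest.append(agent.rest_length)
                spring_k.append(float(agent.get("spine stiffness", 1e5 * FN)))
        hinge_refs = []
        hinge_kappa = []
        hinge_rest = []
        if registry is not None:
            for link in registry.links:
                ia = point_map.get((link.agent_a, link.point_a))
                ib = point_map.get((link.agent_b, link.point_b))
                if ia is None or ib is None:
                    continue
                spring_i.append(ia)
                spring_j.append(ib)
                spring_rest.append(link.rest_length)
                spring_k.append(link.stiffness)
            for hinge in registry.hinges:
                try:
                    refs = tuple(point_map[r] for r in hinge.refs)
                except KeyError:
                    continue
                hinge_refs.append(refs)
                hinge_kappa.append(hinge.stiffness)
                hinge_rest.append(hinge.rest_angle)
        self.pos = np.array(pos, dtype=float)
        self.prad = np.array(prad, dtype=float)
        self.b0 = np.array(body_first, dtype=int)
        self.b1 = np.array(body_second, dtype=int)
        self.brad = np.array(body_rad, dtype=float)
        self.bE = np.array(body_E, dtype=float)
        self.springs = (
            np.array(spring_i, dtype=int),
            np.array(spring_j, dtype=int),
            np.array(spring_rest, dtype=float),
            np.array(spring_k, dtype=float),
        )
        self.hinges = (
            np.array(hinge_refs, dtype=int).reshape(-1, 3),
            np.array(hinge_kappa, dtype=float),
            np.array(hinge_rest, dtype=float),
        )
        self.lengths = np.array(
            [L if np.isfinite(L) else 0.0 for L in domain.lengths]
        )
        self.periodic = np.array(domain.periodic, dtype=bool)
        self.n_bodies = len(agents)
        # pair cache: valid while bodies drift less than _pair_slack since build
        self._pair_slack = 0.25
        self._pair_ref: np.ndarray | None = None
        self._pair_cache: tuple[np.ndarray, np.ndarray] | None = None

    def pairs(self, pos: np.ndarray, margin: float) -> tuple[np.ndarray, np.ndarray]:
        """Candidate body pairs, cached across small position drifts."""
        if self._pair_cache is not None and self._pair_ref is not None:
            drift = float(np.abs(pos - self._pair_ref).max(initial=0.0))
            if drift < self._pair_slack:
                return self._pair_cache
        saved = self.pos
        self.pos = pos
        try:
            self._pair_cache = self.candidate_pairs(margin + 2.0 * self._pair_slack)
        finally:
            self.pos = saved
        self._pair_ref = pos.copy()
        return self._pair_cache

    # -- candidate pairs via uniform cell binning -------------------------
    def candidate_pairs(self, margin: float) -> tuple[np.ndarray, np.ndarray]:
        centers = 0.5 * (self.pos[self.b0] + self.pos[self.b1])
        half_extent = (
            0.5 * np.linalg.norm(self.pos[self.b1] - self.pos[self.b0], axis=1)
            + self.brad
        )
        cs = max(2.0 * float(half_extent.max(initial=0.1)) + margin, 1e-6)
        ncell = np.ones(self.dim, dtype=int)
        cell_size = np.full(self.dim, cs)
        for ax in range(self.dim):
            L = self.lengths[ax]
            if self.periodic[ax] and L > 0:
                ncell[ax] = max(1, int(L // cs))
                cell_size[ax] = L / ncell[ax]
        coords = centers.copy()
        for ax in range(self.dim):
            if self.periodic[ax] and self.lengths[ax] > 0:
                coords[:, ax] = np.mod(coords[:, ax], self.lengths[ax])
        cells = np.floor(coords / cell_size).astype(int)
        buckets: dict[tuple, list[int]] = {}
        for i, c in enumerate(map(tuple, cells)):
            buckets.setdefault(c, []).append(i)
        offsets = [
            off
            for off in itertools.product((-1, 0, 1), repeat=self.dim)
            if off > tuple([0] * self.dim) or off == tuple([0] * self.dim)
        ]
        ia_all, ib_all = [], []
        for cell, members in buckets.items():
            arr = np.array(members)
            for off in offsets:
                target = list(cell)
                ok = True
                for ax in range(self.dim):
                    target[ax] += off[ax]
                    if self.periodic[ax] and self.lengths[ax] > 0:
                        target[ax] %= ncell[ax]
                other = buckets.get(tuple(target))
                if other is None:
                    continue
                brr = np.array(other)
                if off == tuple([0] * self.dim):
                    if len(arr) > 1:
                        iu, ju = np.triu_indices(len(arr), k=1)
                        ia_all.append(arr[iu])
                        ib_all.append(arr[ju])
                else:
                    if tuple(target) == cell:
                        continue  # wrapped onto itself (single periodic cell)
                    ia = np.repeat(arr, len(brr))
                    ib = np.tile(brr, len(arr))
                    ia_all.append(ia)
                    ib_all.append(ib)
        if not ia_all:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        ia = np.concatenate(ia_all)
        ib = np.concatenate(ib_all)
        keep = ia != ib
        lo = np.minimum(ia, ib)[keep]
        hi = np.maximum(ia, ib)[keep]
        uniq = np.unique(lo * self.n_bodies + hi)
        return uniq // self.n_bodies, uniq % self.n_bodies

    def _min_image(self, delta: np.ndarray) -> np.ndarray:
        for ax in range(self.dim):
            if self.periodic[ax] and self.lengths[ax] > 0:
                L = self.lengths[ax]
                delta[:, ax] -= L * np.round(delta[:, ax] / L)
        return delta

    # -- force sweep -------------------------------------------------------
    def forces(self, pos: np.ndarray, planes: list[Plane]) -> tuple[np.ndarray, float]:
        F = np.zeros_like(pos)
        max_xi = 0.0
        ia, ib = self.pairs(pos, margin=0.1)
        if len(ia):
            p1 = pos[self.b0[ia]]
            q1 = pos[self.b1[ia]]
            p2 = pos[self.b0[ib]]
            q2 = pos[self.b1[ib]]
            shift = self._min_image(
                0.5 * (p2 + q2) - 0.5 * (p1 + q1)
            ) - (0.5 * (p2 + q2) - 0.5 * (p1 + q1))
            p2 = p2 + shift
            q2 = q2 + shift
            s, t = _segment_segment_params(p1, q1, p2, q2)
            wa = p1 + s[:, None] * (q1 - p1)
            wb = p2 + t[:, None] * (q2 - p2)
            d = wa - wb
            dist = np.linalg.norm(d, axis=1)
            xi = self.brad[ia] + self.brad[ib] - dist
            hit = xi > 0
            if np.any(hit):
                max_xi = max(max_xi, float(xi[hit].max()))
                d = d[hit]
                dist = dist[hit]
                xi = xi[hit]
                s_h, t_h = s[hit], t[hit]
                ia_h, ib_h = ia[hit], ib[hit]
                normal = np.where(
                    dist[:, None] > 1e-12,
                    d / np.maximum(dist, 1e-12)[:, None],
                    _tie_normal(len(d), self.dim),
                )
                ra, rb = self.brad[ia_h], self.brad[ib_h]
                r_eff = ra * rb / (ra + rb)
                Ea, Eb = self.bE[ia_h], self.bE[ib_h]
                e_eff = Ea * Eb / (Ea + Eb)
                mag = 4.0 / 3.0 * r_eff * e_eff * xi**1.5
                fvec = normal * mag[:, None]
                np.add.at(F, self.b0[ia_h], fvec * (1 - s_h)[:, None])
                np.add.at(F, self.b1[ia_h], fvec * s_h[:, None])
                np.add.at(F, self.b0[ib_h], -fvec * (1 - t_h)[:, None])
                np.add.at(F, self.b1[ib_h], -fvec * t_h[:, None])
        # solid boundary planes (infinite radius, infinite modulus)
        for plane in planes:
            n = np.asarray(plane.normal, dtype=float)
            n = n / np.linalg.norm(n)
            signed = pos @ n - plane.offset
            xi = self.prad - signed
            hit = xi > 0
            if np.any(hit):
                max_xi = max(max_xi, float(xi[hit].max()))
                # r_eff = r_point, E_eff = E of the owning body
                point_E = np.empty(len(pos))
                point_E[self.b0] = self.bE
                point_E[self.b1] = self.bE
                mag = 4.0 / 3.0 * self.prad[hit] * point_E[hit] * xi[hit] ** 1.5
                F[hit] += mag[:, None] * n[None, :]
        # springs (rod spines + filament connections)
        si, sj, rest, k = self.springs
        if len(si):
            d = self._min_image(pos[sj] - pos[si])
            dist = np.linalg.norm(d, axis=1)
            u = d / np.maximum(dist, 1e-12)[:, None]
            dl = dist - rest
            fvec = (k * dl)[:, None] * u
            np.add.at(F, si, fvec)
            np.add.at(F, sj, -fvec)
        # torsion hinges
        refs, kappa, rest_angle = self.hinges
        if len(refs):
            f1, f2, f3 = _hinge_forces(pos, refs, kappa, rest_angle, self._min_image)
            np.add.at(F, refs[:, 0], f1)
            np.add.at(F, refs[:, 1], f2)
            np.add.at(F, refs[:, 2], f3)
        return F, max_xi

    def max_overlap(self, pos: np.ndarray) -> float:
        ia, ib = self.pairs(pos, margin=0.0)
        if not len(ia):
            return 0.0
        p1, q1 = pos[self.b0[ia]], pos[self.b1[ia]]
        p2, q2 = pos[self.b0[ib]], pos[self.b1[ib]]
        shift = self._min_image(0.5 * (p2 + q2) - 0.5 * (p1 + q1)) - (
            0.5 * (p2 + q2) - 0.5 * (p1 + q1)
        )
        p2 = p2 + shift
        q2 = q2 + shift
        s, t = _segment_segment_params(p1, q1, p2, q2)
        wa = p1 + s[:, None] * (q1 - p1)
        wb = p2 + t[:, None] * (q2 - p2)
        dist = np.linalg.norm(wa - wb, axis=1)
        xi = self.brad[ia] + self.brad[ib] - dist
        return float(max(0.0, xi.max(initial=0.0)))

    def writeback(self, pos: np.ndarray) -> None:
        pos = self.domain.wrap_position(pos)
        k = 0
        for agent in self.agents:
            for p in agent.points:
                p.position = pos[k].copy()
                k += 1


def _tie_normal(n: int, dim: int) -> np.ndarray:
    out = np.zeros((n, dim))
    out[:, 0] = 1.0
    return out


def _segment_segment_params(p1, q1, p2, q2):
    """Vectorized clamped closest-point parameters of segment pairs.

    Degenerate (zero-length) segments reduce to points; spheres are
    represented as zero-length segments so one kernel covers all pairs.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    eps = 1e-18
    a_deg = a <= eps
    e_deg = e <= eps
    denom = a * e - b * b
    safe_denom = np.where(denom > eps, denom, 1.0)
    s = np.where(denom > eps, np.clip((b * f - c * e) / safe_denom, 0.0, 1.0), 0.0)
    safe_e = np.where(e_deg, 1.0, e)
    t = (b * s + f) / safe_e
    t_low = t < 0.0
    t_high = t > 1.0
    safe_a = np.where(a_deg, 1.0, a)
    s = np.where(t_low, np.clip(-c / safe_a, 0.0, 1.0), s)
    s = np.where(t_high, np.clip((b - c) / safe_a, 0.0, 1.0), s)
    t = np.clip(t, 0.0, 1.0)
    s = np.where(a_deg, 0.0, s)
    t = np.where(e_deg, 0.0, np.where(a_deg, np.clip(f / safe_e, 0.0, 1.0), t))
    return s, t


def _hinge_forces(pos, refs, kappa, rest, min_image):
    r1 = min_image(pos[refs[:, 0]] - pos[refs[:, 1]])
    r3 = min_image(pos[refs[:, 2]] - pos[refs[:, 1]])
    L1 = np.linalg.norm(r1, axis=1)
    L3 = np.linalg.norm(r3, axis=1)
    ok = (L1 > 1e-12) & (L3 > 1e-12)
    L1s = np.maximum(L1, 1e-12)
    L3s = np.maximum(L3, 1e-12)
    u1 = r1 / L1s[:, None]
    u3 = r3 / L3s[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", u1, u3), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dtheta = theta - rest
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    degen = sin_t < 1e-9
    sin_s = np.where(degen, 1.0, sin_t)
    d1 = (u3 - cos_t[:, None] * u1) / sin_s[:, None]
    d3 = (u1 - cos_t[:, None] * u3) / sin_s[:, None]
    scale = np.where(ok & ~degen, kappa * dtheta, 0.0)
    f1 = scale[:, None] * d1 / L1s[:, None]
    f3 = scale[:, None] * d3 / L3s[:, None]
    f2 = -(f1 + f3)
    return f1, f2, f3


def relax(
    agents: list[Agent],
    config: RelaxationConfig,
    domain: Domain,
    surfaces: list[Plane] | None = None,
    registry: LinkRegistry | None = None,
) -> RelaxResult:
    """Relax agent positions to mechanical equilibrium (in place)."""
    if not agents:
        return RelaxResult(0, 0.0, 0.0, True)
    planes = list(surfaces or [])
    state = _MechState(agents, domain, registry, config)
    pos = state.pos.copy()
    mu = config.viscosity
    drag = 6.0 * math.pi * state.prad * mu
    # overdamped spring-like modes decay at lambda = k / drag; explicit
    # integration is stable for dt < 2 / lambda.  Spring and hinge
    # stiffnesses are fixed; the Hertzian contact stiffness
    # dF/dxi = 2 r_eff E_eff sqrt(xi) is re-estimated each sweep from the
    # current worst overlap so the internal step can grow as contacts relax.
    k_static = 0.0
    if len(state.springs[3]):
        k_static = max(k_static, float(state.springs[3].max()))
    if len(state.hinges[1]):
        k_static = max(k_static, float(state.hinges[1].max()) / 0.25)
    r_max = float(state.brad.max()) if len(state.brad) else 1.0
    e_max = float(state.bE.max()) if len(state.bE) else 0.0
    residual = 0.0
    converged = False
    iterations = 0
    history: list[float] = []
    for iterations in range(1, config.max_iterations + 1):
        F, max_xi = state.forces(pos, planes)
        residual = float(np.linalg.norm(F, axis=1).max(initial=0.0))
        if residual < config.force_tolerance:
            converged = True
            break
        # jammed packings plateau at a finite residual while overlaps are
        # already negligible: accept once the overlap tolerance is met and
        # the residual has stopped improving
        history.append(residual)
        if (
            max_xi <= config.max_overlap
            and len(history) > 50
            and residual > 0.99 * history[-50]
        ):
            converged = True
            break
        v = F / drag[:, None]
        dt = config.max_step
        if config.stability_cap:
            k_scale = max(k_static, 2.0 * r_max * e_max * math.sqrt(max(max_xi, 1e-12)))
            if k_scale > 0:
                # explicit Euler is stable below 2 drag / k
                dt = min(dt, 0.9 * float(drag.min()) / k_scale)
        if config.max_displacement is not None:
            vmax = float(np.linalg.norm(v, axis=1).max())
            if vmax > 0:
                dt = min(dt, config.max_displacement / vmax)
        if config.integrator == "heun":
            pred = pos + v * dt
            F2, _ = state.forces(pred, planes)
            v2 = F2 / drag[:, None]
            pos = pos + 0.5 * dt * (v + v2)
        else:
            pos = pos + v * dt
    state.writeback(pos)
    return RelaxResult(
        iterations=iterations,
        residual_force=residual,
        max_overlap=state.max_overlap(pos),
        converged=converged,
    )


def shove(
    agents: list[Agent],
    domain: Domain,
    shoving_factor: float = 1.0,
    tolerance: float = 1e-6,
    max_iterations: int = 10000,
) -> RelaxResult:
    """Legacy pairwise shoving for spherical agents.

    Overlapping pairs (actual distance below shoving_factor times the
    contact distance) are displaced half-and-half along the center line;
    iterated until no pair exceeds the tolerance.  Rods and filaments
    are rejected: shoving cannot handle extended morphologies.
    """
    for agent in agents:
        if agent.kind != COCCUS:
            raise UnsupportedMorphologyError(
                f"shoving supports spherical agents only, agent {agent.id} is {agent.kind}"
            )
    if not agents:
        return RelaxResult(0, 0.0, 0.0, True)
    state = _MechState(agents, domain, None, RelaxationConfig())
    pos = state.pos.copy()
    rad = state.brad
    worst = 0.0
    converged = False
    iterations = 0
    margin = float(rad.max(initial=0.0)) * max(0.0, shoving_factor - 1.0) * 2.0 + 0.5
    for iterations in range(1, max_iterations + 1):
        ia, ib = state.pairs(pos, margin=margin)
        disp = np.zeros_like(pos)
        worst = 0.0
        if len(ia):
            d = state._min_image(pos[ib] - pos[ia])
            dist = np.linalg.norm(d, axis=1)
            contact = shoving_factor * (rad[ia] + rad[ib])
            deficit = contact - dist
            hit = deficit > tolerance
            if np.any(hit):
                worst = float(deficit[hit].max())
                u = d[hit] / np.maximum(dist[hit], 1e-12)[:, None]
                half = 0.5 * deficit[hit][:, None] * u
                np.add.at(disp, ia[hit], -half)
                np.add.at(disp, ib[hit], half)
        if worst <= tolerance:
            converged = True
            break
        pos = pos + disp
        for ax in range(state.dim):
            if state.periodic[ax] and state.lengths[ax] > 0:
                pos[:, ax] = np.mod(pos[:, ax], state.lengths[ax])
    state.writeback(pos)
    return RelaxResult(iterations, 0.0, state.max_overlap(pos), converged)
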