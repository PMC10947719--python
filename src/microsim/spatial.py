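"""Spatially explicit compartments: pseudo-steady-state reaction-diffusion.

Solutes live on a uniform Cartesian grid (voxel-centered finite
volumes).  Because diffusion and reaction equilibrate orders of
magnitude faster than biomass change, each solute field is solved to
stationarity at frozen biomass::

    div( omega(x) grad S(x) ) + q(x, S) = 0

with harmonic-mean face diffusivities (correct for discontinuities at
the biofilm boundary) and the six boundary types: solid (no-flux),
fixed-value (Dirichlet), periodic, connected (Dirichlet at the linked
well-mixed compartment's concentration, with the boundary flux fed back
into its ODE), and in/outflow which only apply to well-mixed
compartments.  Nonlinear kinetics are handled by damped Picard
iterations with a diagonal Newton linearization of dq/dS.

Agent-catalyzed reactions contribute to the voxel containing the
agent's center of gravity (half-open voxels [i*h, (i+1)*h); a position
exactly on the upper domain face belongs to the last voxel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .agents import Agent, LinkRegistry
from .geometry import Domain
from .mechanics import Plane
from .reactions import AGENT, ENVIRONMENT, Reaction, clamped_bindings

__all__ = ["BoundarySpec", "SoluteField", "SpatialCompartment", "PdeError"]


class PdeError(RuntimeError):
    pass


@dataclass
class BoundarySpec:
    kind: str  # 'noflux' | 'dirichlet' | 'periodic' | 'connected'
    values: dict[str, float] = field(default_factory=dict)
    compartment: str | None = None

    def __post_init__(self):
        if self.kind not in ("noflux", "dirichlet", "periodic", "connected"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")


@dataclass
class SoluteField:
    name: str
    diffusivity: float  # um^2/h in water
    field: np.ndarray | None = None
    biofilm_diffusivity_factor: float = 1.0  # relative diffusivity inside biomass


class SpatialCompartment:
    def __init__(
        self,
        name: str,
        extents: tuple[float, ...],
        resolution: float,
        boundaries: dict[tuple[int, int], BoundarySpec] | None = None,
        thickness: float = 1.0,
        scale_factor: float = 1.0,
        parameters: dict[str, float] | None = None,
        scale_2d: bool = True,
    ):
        self.name = name
        self.extents = tuple(float(e) for e in extents)
        self.resolution = float(resolution)
        self.dim = len(self.extents)
        self.shape = tuple(int(round(e / resolution)) for e in self.extents)
        for e, n in zip(self.extents, self.shape):
            if abs(n * resolution - e) > 1e-9 * max(1.0, e):
                raise ValueError(
                    f"resolution {resolution} does not divide extent {e}"
                )
        self.thickness = thickness if self.dim == 2 else 1.0
        self.scale_factor = scale_factor
        self.scale_2d = scale_2d
        self.parameters = dict(parameters or {})
        self.boundaries: dict[tuple[int, int], BoundarySpec] = dict(boundaries or {})
        for ax in range(self.dim):
            for side in (0, 1):
                self.boundaries.setdefault((ax, side), BoundarySpec("noflux"))
        self._check_periodic_pairs()
        self.solutes: dict[str, SoluteField] = {}
        self.reactions: list[Reaction] = []
        self.agents: list[Agent] = []
        self.registry = LinkRegistry()
        self.boundary_fluxes: dict[str, float] = {}  # per solute, fg/h into domain
        self.last_solve: dict[str, Any] = {}

    def _check_periodic_pairs(self):
        for ax in range(self.dim):
            kinds = {self.boundaries[(ax, s)].kind == "periodic" for s in (0, 1)}
            if kinds == {True, False}:
                raise ValueError(f"periodic boundary on axis {ax} must come in a pair")

    # -- basic structure ---------------------------------------------------
    @property
    def periodic(self) -> tuple[bool, ...]:
        return tuple(
            self.boundaries[(ax, 0)].kind == "periodic" for ax in range(self.dim)
        )

    @property
    def domain(self) -> Domain:
        return Domain(self.extents, self.periodic)

    @property
    def voxel_volume(self) -> float:
        return self.resolution**self.dim * self.thickness

    def surfaces(self) -> list[Plane]:
        """Solid planes agents collide with (the no-flux faces)."""
        planes = []
        for (ax, side), spec in self.boundaries.items():
            if spec.kind != "noflux":
                continue
            normal = [0.0] * self.dim
            if side == 0:
                normal[ax] = 1.0
                planes.append(Plane(tuple(normal), 0.0))
            else:
                normal[ax] = -1.0
                planes.append(Plane(tuple(normal), -self.extents[ax]))
        return planes

    def add_solute(self, solute: SoluteField, initial: float = 0.0) -> None:
        if solute.field is None:
            solute.field = np.full(self.shape, float(initial))
        self.solutes[solute.name] = solute

    def add_reaction(self, reaction: Reaction) -> None:
        for sp_name in reaction.stoichiometry:
            if sp_name not in self.solutes and sp_name != "mass":
                raise KeyError(
                    f"reaction {reaction.name!r} references undeclared solute {sp_name!r}"
                )
        self.reactions.append(reaction)

    # -- agents on the grid ------------------------------------------------
    def voxel_of(self, position: np.ndarray) -> tuple[int, ...]:
        idx = []
        for ax in range(self.dim):
            x = float(position[ax])
            if x < 0.0 or x > self.extents[ax] + 1e-9:
                raise PdeError(
                    f"agent position {position} outside domain {self.extents}"
                    " (boundary application bug)"
                )
            i = int(x // self.resolution)
            idx.append(min(i, self.shape[ax] - 1))
        return tuple(idx)

    def map_biomass_to_grid(
        self, concentrations: dict[str, np.ndarray] | None = None
    ) -> tuple[dict[str, np.ndarray], dict[int, float]]:
        """Agent reaction rates on the grid at given (or current) fields.

        Returns per-solute volumetric rate fields q (fg/um^3/h) and the
        per-agent biomass growth rate (fg/h).
        """
        conc = concentrations or {n: s.field for n, s in self.solutes.items()}
        q = {n: np.zeros(self.shape) for n in self.solutes}
        growth: dict[int, float] = {}
        vv = self.voxel_volume
        for agent in self.agents:
            if agent.get("inactive"):
                continue
            vox = self.voxel_of(agent.center)
            bindings = {n: float(conc[n][vox]) for n in conc}
            bindings = clamped_bindings(bindings)
            bindings.update(self.parameters)
            for name, value in agent.resolved_aspects().items():
                if isinstance(value, (int, float)):
                    bindings.setdefault(name, float(value))
            bindings["mass"] = agent.mass
            rate_mass = 0.0
            for rxn in agent.get("reactions", []):
                if rxn.catalyst != AGENT:
                    continue
                r = rxn.rate_value(bindings)
                for sp_name, coeff in rxn.stoichiometry.items():
                    if sp_name == "mass":
                        rate_mass += coeff * r
                    elif sp_name in q:
                        q[sp_name][vox] += coeff * r / vv
            growth[agent.id] = growth.get(agent.id, 0.0) + rate_mass
        return q, growth

    def _env_rate_fields(
        self, conc: dict[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        q = {n: np.zeros(self.shape) for n in self.solutes}
        env = [r for r in self.reactions if r.catalyst == ENVIRONMENT]
        if not env:
            return q
        flat = {n: np.maximum(conc[n], 0.0).ravel() for n in conc}
        ncell = flat[next(iter(flat))].shape[0] if flat else 0
        for i in range(ncell):
            bindings = {n: float(flat[n][i]) for n in flat}
            bindings.update(self.parameters)
            for rxn in env:
                r = rxn.rate_value(bindings)
                for sp_name, coeff in rxn.stoichiometry.items():
                    if sp_name in q:
                        q[sp_name].ravel()[i] += coeff * r
        return q

    def biomass_region(self) -> np.ndarray:
        """Boolean field: voxels containing at least one agent center."""
        mask = np.zeros(self.shape, dtype=bool)
        for agent in self.agents:
            mask[self.voxel_of(agent.center)] = True
        return mask

    # -- linear diffusion operator ----------------------------------------
    def _assemble(
        self, solute: SoluteField, linked_values: dict[str, float] | None = None
    ) -> tuple[sp.csr_matrix, np.ndarray, bool]:
        """Sparse operator A and boundary vector g with A S + g = div(w grad S).

        The third element reports whether any value-setting (Dirichlet or
        connected) face exists; without one the operator is singular
        (pure Neumann) and steady states are only defined up to the mass
        constraint.
        """
        h = self.resolution
        shape = self.shape
        n = int(np.prod(shape))
        omega = np.full(shape, solute.diffusivity)
        if solute.biofilm_diffusivity_factor != 1.0:
            omega = np.where(
                self.biomass_region(),
                solute.diffusivity * solute.biofilm_diffusivity_factor,
                solute.diffusivity,
            )
        om = omega.ravel()
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        g = np.zeros(n)
        has_value_bc = False
        idx = np.arange(n).reshape(shape)
        for ax in range(self.dim):
            # interior faces
            sl_lo = [slice(None)] * self.dim
            sl_hi = [slice(None)] * self.dim
            sl_lo[ax] = slice(0, shape[ax] - 1)
            sl_hi[ax] = slice(1, shape[ax])
            i_lo = idx[tuple(sl_lo)].ravel()
            i_hi = idx[tuple(sl_hi)].ravel()
            w = 2.0 * om[i_lo] * om[i_hi] / (om[i_lo] + om[i_hi]) / h**2
            rows += [i_lo, i_lo, i_hi, i_hi]
            cols += [i_hi, i_lo, i_lo, i_hi]
            vals += [w, -w, w, -w]
            for side in (0, 1):
                spec = self.boundaries[(ax, side)]
                sl = [slice(None)] * self.dim
                sl[ax] = 0 if side == 0 else shape[ax] - 1
                cells = idx[tuple(sl)].ravel()
                if spec.kind == "periodic":
                    if side == 1:
                        continue  # handled once per axis
                    sl2 = [slice(None)] * self.dim
                    sl2[ax] = shape[ax] - 1
                    other = idx[tuple(sl2)].ravel()
                    if shape[ax] < 2:
                        continue
                    w = 2.0 * om[cells] * om[other] / (om[cells] + om[other]) / h**2
                    rows += [cells, cells, other, other]
                    cols += [other, cells, cells, other]
                    vals += [w, -w, w, -w]
                elif spec.kind in ("dirichlet", "connected"):
                    has_value_bc = True
                    if spec.kind == "dirichlet":
                        value = spec.values.get(solute.name, 0.0)
                    else:
                        value = (linked_values or {}).get(solute.name, 0.0)
                    w = 2.0 * om[cells] / h**2  # ghost value at the face, h/2 away
                    rows += [cells]
                    cols += [cells]
                    vals += [-w]
                    g[cells] += w * value
                # noflux: nothing
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return A, g, has_value_bc

    # -- steady-state solve ------------------------------------------------
    def solve_steady_state(
        self,
        linked_values: dict[str, dict[str, float]] | None = None,
        tol: float = 1e-9,
        max_iter: int = 200,
        damping: float = 1.0,
        pin_bulk_above: float | None = None,
    ) -> dict[int, float]:
        """Solve all solute fields to stationarity at frozen biomass.

        Returns the per-agent biomass growth rates (fg/h) at the converged
        fields.  ``pin_bulk_above``: optional height above which the field
        is pinned to the top-boundary value (well-mixed bulk region above
        the concentration boundary layer).

        Raises :class:`PdeError` on non-convergence (never returns a
        clamped or unconverged field silently).
        """
        names = list(self.solutes)
        if not names:
            return {}
        n = int(np.prod(self.shape))
        conc = {m: self.solutes[m].field.copy() for m in names}
        ops = {}
        for m in names:
            lv = (linked_values or {}).get(self.name, {})
            ops[m] = self._assemble(self.solutes[m], lv)
        pin_mask = None
        if pin_bulk_above is not None and self.dim >= 1:
            ax = self.dim - 1  # vertical axis is the last one
            centers = (np.arange(self.shape[ax]) + 0.5) * self.resolution
            mask = np.zeros(self.shape, dtype=bool)
            sl = [slice(None)] * self.dim
            sl[ax] = centers > pin_bulk_above
            mask[tuple(sl)] = True
            pin_mask = mask.ravel()
        growth: dict[int, float] = {}
        eps_rel = 1e-6
        max_delta = math.inf
        iteration = -1
        for iteration in range(max_iter):
            q_env = self._env_rate_fields(conc)
            q_ag, growth = self.map_biomass_to_grid(conc)
            max_delta = 0.0
            for m in names:
                A, gvec, has_bc = ops[m]
                q = (q_env[m] + q_ag[m]).ravel()
                # diagonal Newton linearization dq/dS_m (finite difference)
                scale = max(float(np.abs(conc[m]).max()), 1e-12)
                d_conc = dict(conc)
                d_conc[m] = conc[m] + eps_rel * scale
                q_env2 = self._env_rate_fields(d_conc)
                q_ag2, _ = self.map_biomass_to_grid(d_conc)
                dq = (
                    (q_env2[m] + q_ag2[m]).ravel() - q
                ) / (eps_rel * scale)
                dq = np.minimum(dq, 0.0)  # keep the Jacobian negative semidefinite
                S_k = conc[m].ravel()
                M = A + sp.diags(dq)
                rhs = -(gvec + q - dq * S_k)
                pinned = pin_mask is not None
                if pinned:
                    top_spec = self.boundaries[(self.dim - 1, 1)]
                    bulk = top_spec.values.get(m, 0.0)
                    if top_spec.kind == "connected":
                        bulk = (linked_values or {}).get(self.name, {}).get(m, 0.0)
                    M = M.tolil()
                    for i in np.where(pin_mask)[0]:
                        M.rows[i] = [i]
                        M.data[i] = [1.0]
                        rhs[i] = bulk
                    M = M.tocsr()
                S_new = self._solve_linear(
                    M, rhs, S_k, symmetric=not pinned, closed=not has_bc and not pinned,
                    name=m,
                )
                if not np.all(np.isfinite(S_new)):
                    raise PdeError(f"steady-state solve diverged for {m!r}")
                S_new = S_k + damping * (S_new - S_k)
                # clamp inside iterations only; the converged field must
                # satisfy the discrete equation without clamping
                S_new = np.maximum(S_new, 0.0)
                max_delta = max(
                    max_delta, float(np.abs(S_new - S_k).max()) / max(scale, 1e-30)
                )
                conc[m] = S_new.reshape(self.shape)
            if max_delta < tol:
                break
        else:
            raise PdeError(
                f"steady-state iterations did not converge in {self.name!r}: "
                f"last relative change {max_delta:.3e} > tol {tol:.1e}"
            )
        # verify the converged fields satisfy the discrete balance
        q_env = self._env_rate_fields(conc)
        q_ag, growth = self.map_biomass_to_grid(conc)
        residuals = {}
        for m in names:
            A, gvec, _ = ops[m]
            res = A @ conc[m].ravel() + gvec + (q_env[m] + q_ag[m]).ravel()
            scale = max(
                float((np.abs(A) @ np.abs(conc[m].ravel())).max()),
                float(np.abs(gvec).max()),
                float(np.abs(q_env[m] + q_ag[m]).max()),
                1e-30,
            )
            residuals[m] = float(np.abs(res).max()) / scale
            if residuals[m] > 1e-5:
                raise PdeError(
                    f"converged field {m!r} violates the steady balance: "
                    f"relative residual {residuals[m]:.3e}"
                )
            self.solutes[m].field = conc[m]
        self.last_solve = {"residuals": residuals}
        self._record_boundary_fluxes(linked_values)
        self.last_solve.update({"iterations": iteration + 1, "max_delta": max_delta})
        return growth

    def _solve_linear(
        self,
        M: sp.csr_matrix,
        rhs: np.ndarray,
        x0: np.ndarray,
        symmetric: bool,
        closed: bool,
        name: str,
    ) -> np.ndarray:
        """One linear solve; -M is SPD for value-BC problems, so CG applies.

        Closed (pure Neumann) systems are singular: the mean of the field
        is fixed to conserve total solute mass; an inconsistent source
        distribution is caught by the residual check afterwards.
        """
        from scipy.sparse.linalg import cg

        if closed:
            n = M.shape[0]
            Ml = M.tolil()
            Ml.rows[n - 1] = list(range(n))
            Ml.data[n - 1] = [1.0 / n] * n
            rhs = rhs.copy()
            rhs[n - 1] = float(x0.mean())
            return spsolve(Ml.tocsr(), rhs)
        if symmetric:
            x, info = cg(-M, -rhs, x0=x0, rtol=1e-13, atol=0.0, maxiter=4 * M.shape[0])
            if info == 0 and np.all(np.isfinite(x)):
                return x
        return spsolve(M, rhs)

    def _record_boundary_fluxes(self, linked_values) -> None:
        """Diffusive flux (fg/h, positive into the domain) per connected face."""
        h = self.resolution
        self.boundary_fluxes = {m: 0.0 for m in self.solutes}
        face_area = self.voxel_volume / h
        for (ax, side), spec in self.boundaries.items():
            if spec.kind != "connected":
                continue
            for m, sol in self.solutes.items():
                value = (linked_values or {}).get(self.name, {}).get(m, 0.0)
                sl = [slice(None)] * self.dim
                sl[ax] = 0 if side == 0 else self.shape[ax] - 1
                cells = sol.field[tuple(sl)].ravel()
                flux = float(np.sum(2.0 * sol.diffusivity / h * (value - cells)))
                self.boundary_fluxes[m] += flux * face_area * self.scale_factor

    # -- transient integration (pseudo-steady-state consistency check) ----
    def integrate_transient(self, t_end: float, rtol: float = 1e-8) -> None:
        """Method-of-lines integration of the full parabolic problem."""
        from scipy.integrate import solve_ivp

        names = list(self.solutes)
        n = int(np.prod(self.shape))
        ops = {m: self._assemble(self.solutes[m]) for m in names}
        y0 = np.concatenate([self.solutes[m].field.ravel() for m in names])

        def rhs(t, y):
            conc = {
                m: y[i * n : (i + 1) * n].reshape(self.shape)
                for i, m in enumerate(names)
            }
            q_env = self._env_rate_fields(conc)
            q_ag, _ = self.map_biomass_to_grid(conc)
            out = []
            for i, m in enumerate(names):
                A, g, _ = ops[m]
                out.append(A @ y[i * n : (i + 1) * n] + g + (q_env[m] + q_ag[m]).ravel())
            return np.concatenate(out)

        sol = solve_ivp(rhs, (0, t_end), y0, method="LSODA", rtol=rtol, atol=1e-12)
        if not sol.success:
            raise PdeError(f"transient integration failed: {sol.message}")
        y = sol.y[:, -1]
        for i, m in enumerate(names):
            self.solutes[m].field = y[i * n : (i + 1) * n].reshape(self.shape)

    # -- agent bookkeeping -------------------------------------------------
    def wrap_agents(self) -> None:
        dom = self.domain
        for agent in self.agents:
            for p in agent.points:
                p.position = dom.wrap_position(p.position)

    def total_solute_mass(self, name: str) -> float:
        return float(self.solutes[name].field.sum()) * self.voxel_volume
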