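"""Force models: Hertzian contact, linear and torsion springs, Stokes drag.

All quantities are in base units (um, fg, h); convenient magnitudes:
1 fN ~ 1.296e16 fg um / h^2, 1 Pa ~ 1.296e19 fg / (um h^2),
1 Pa s ~ 3.6e15 fg / (um h).
"""

from __future__ import annotations

import math

import numpy as np

from .units import to_base

__all__ = [
    "FN",
    "PA",
    "PA_S",
    "hertz_force",
    "hooke_spring",
    "torsion_spring",
    "torsion_forces",
    "terminal_velocity",
    "effective_radius",
    "effective_modulus",
]

FN = to_base("1 fN")
PA = to_base("1 Pa")
PA_S = to_base("1 Pa s")


def hertz_force(r_eff: float, e_eff: float, xi: float) -> float:
    """Hertzian soft-sphere repulsion F = (4/3) r_eff E_eff xi^(3/2).

    ``xi`` is the overlap; non-positive overlap gives zero force.
    """
    if xi <= 0.0:
        return 0.0
    return 4.0 / 3.0 * r_eff * e_eff * xi**1.5


def effective_radius(r_a: float, r_b: float = math.inf) -> float:
    """Harmonic combination r_a r_b / (r_a + r_b); a plane has r = inf."""
    if math.isinf(r_b):
        return r_a
    return r_a * r_b / (r_a + r_b)


def effective_modulus(e_a: float, e_b: float = math.inf) -> float:
    if math.isinf(e_b):
        return e_a
    return e_a * e_b / (e_a + e_b)


def hooke_spring(k: float, delta_l: float) -> float:
    """Linear spring force magnitude F = k |dl| (restoring)."""
    return k * delta_l


def torsion_spring(kappa: float, delta_theta: float, arm_length: float) -> float:
    """Angular Hooke's law: F = kappa dtheta / L applied at the arm ends."""
    if arm_length <= 0:
        raise ValueError("torsion arm length must be positive")
    return kappa * delta_theta / arm_length


def torsion_forces(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    kappa: float,
    rest_angle: float = math.pi,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forces of an angular spring acting on three chained points.

    The spring derives from the potential U = 1/2 kappa (theta - theta0)^2
    with theta the angle at the middle point p2.  The analytic gradient
    gives end forces of magnitude kappa |dtheta| / L_i perpendicular to
    the respective arm, and the middle point takes minus their sum, so
    net force and net torque across the triple vanish identically.
    """
    r1 = p1 - p2
    r3 = p3 - p2
    L1 = float(np.linalg.norm(r1))
    L3 = float(np.linalg.norm(r3))
    if L1 < 1e-12 or L3 < 1e-12:
        z = np.zeros_like(p1)
        return z, z.copy(), z.copy()
    u1 = r1 / L1
    u3 = r3 / L3
    cos_t = float(np.clip(u1 @ u3, -1.0, 1.0))
    theta = math.acos(cos_t)
    dtheta = theta - rest_angle
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    if sin_t < 1e-9:
        if abs(dtheta) < 1e-9:
            z = np.zeros_like(p1)
            return z, z.copy(), z.copy()
        # straight/folded chain out of rest: pick a deterministic normal
        trial = np.zeros_like(u1)
        trial[int(np.argmin(np.abs(u1)))] = 1.0
        d1 = trial - (trial @ u1) * u1
        d1 /= np.linalg.norm(d1)
        d3 = d1.copy()
    else:
        d1 = (u3 - cos_t * u1) / sin_t
        d3 = (u1 - cos_t * u3) / sin_t
    f1 = kappa * dtheta * d1 / L1
    f3 = kappa * dtheta * d3 / L3
    f2 = -(f1 + f3)
    return f1, f2, f3


def terminal_velocity(
    net_force: np.ndarray, cell_radius: float, viscosity: float
) -> np.ndarray:
    """Stokes-law terminal velocity v = sum(F) / (6 pi r_c mu_f)."""
    if cell_radius <= 0 or viscosity <= 0:
        raise ValueError("radius and viscosity must be positive")
    return np.asarray(net_force, dtype=float) / (6.0 * math.pi * cell_radius * viscosity)
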