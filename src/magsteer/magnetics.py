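"""Coil magnetic fields, particle magnetization and magnetophoretic drift.

The field of each electromagnet is modelled as that of an infinitely thin
circular current loop with ``turns`` windings.  In cylindrical coordinates
(rho, z) attached to the loop, the field components are semi-analytic
expressions in the complete elliptic integrals K(m) and E(m) with parameter

    m = k**2 = 4 a rho / ((a + rho)**2 + z**2)

(the *modulus-squared* convention, i.e. what :func:`scipy.special.ellipk`
expects).  The spatial Jacobian dH/dx is obtained analytically using

    dK/dm = -K/(2m) - E/(2m(m-1)),     dE/dm = (E - K)/(2m)

followed by the cylindrical-to-cartesian coordinate transform.

A suspended superparamagnetic particle carries a moment m = g(H) H aligned
with the local field, where g follows from the Langevin magnetization curve.
The magnetic body force is the point-dipole ("magnetic charge") expression
F = (m . grad) B, and the inertialess drift velocity through the carrier
fluid follows from Stokes drag, v = F / (6 pi eta R_p) + v_f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe, ellipk

__all__ = [
    "MU0",
    "KB",
    "PhysicalConstants",
    "CoilSpec",
    "ParticleSpec",
    "FieldSample",
    "coil_field",
    "coil_field_many",
    "total_field",
    "total_field_arrays",
    "langevin",
    "magnetization",
    "moment_coefficient",
    "magnetic_force",
    "drift_velocity",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants (CODATA / SI-exact values)."""

    mu0: float = 4.0e-7 * math.pi  # vacuum permeability, T m / A
    kB: float = 1.380649e-23       # Boltzmann constant, J / K


CONSTANTS = PhysicalConstants()
MU0 = CONSTANTS.mu0
KB = CONSTANTS.kB

#: evaluation points closer than this to the filament are treated as singular
_FILAMENT_TOL = 1e-9
#: below this cylindrical radius the on-axis closed form is used
_AXIS_TOL = 1e-9
#: Taylor-branch switch for the Langevin function
_LANGEVIN_SMALL = 1e-4


@dataclass(frozen=True)
class CoilSpec:
    """Geometry of one circular electromagnet.

    Parameters
    ----------
    center : array-like of 3 floats
        Position of the loop center, m.
    axis : array-like of 3 floats
        Unit vector along the loop axis.
    radius : float
        Loop radius ``a``, m.
    turns : int
        Number of windings; the field scales with ``turns * current``.
    """

    center: np.ndarray
    axis: np.ndarray
    radius: float
    turns: int

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        if not (np.all(np.isfinite(center)) and np.all(np.isfinite(axis))):
            raise ValueError("coil center/axis must be finite")
        norm = float(np.linalg.norm(axis))
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"coil axis must be a unit vector, |axis| = {norm!r}")
        if not self.radius > 0:
            raise ValueError("coil radius must be positive")
        if int(self.turns) < 1 or int(self.turns) != self.turns:
            raise ValueError("turns must be a positive integer")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "radius", float(self.radius))
        object.__setattr__(self, "turns", int(self.turns))


@dataclass(frozen=True)
class ParticleSpec:
    """Physical parameters of the magnetic nanoparticles.

    ``core_volume`` is derived from the core diameter (sphere, pi d^3 / 6).
    The hydrodynamic radius defaults to the core radius.
    """

    core_diameter: float
    saturation_magnetization: float
    temperature: float = 300.0
    hydrodynamic_radius: float | None = None

    def __post_init__(self) -> None:
        if self.hydrodynamic_radius is None:
            object.__setattr__(self, "hydrodynamic_radius", self.core_diameter / 2.0)
        for name in ("core_diameter", "saturation_magnetization", "temperature",
                     "hydrodynamic_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def core_volume(self) -> float:
        """Particle core volume V = pi d^3 / 6, m^3."""
        return math.pi * self.core_diameter**3 / 6.0


@dataclass(frozen=True)
class FieldSample:
    """Magnetic field and its spatial Jacobian at one point.

    ``H`` is the field in A/m and ``jacobian[i, j] = dH_i / dx_j`` in 1/m
    times A/m.  ``B`` is the flux density mu0 * H in tesla.
    """

    H: np.ndarray
    jacobian: np.ndarray

    @property
    def B(self) -> np.ndarray:
        return MU0 * self.H


# ---------------------------------------------------------------------------
# circular-loop field: cylindrical components and partial derivatives
# ---------------------------------------------------------------------------

def _loop_cyl(ampere_turns: float, a: float, rho: np.ndarray, z: np.ndarray):
    """H_rho, H_z and their rho/z partials for a circular loop.

    ``ampere_turns`` is N * I.  ``rho`` must be bounded away from zero; the
    on-axis limit is handled by the caller.  The closed forms below were
    generated symbolically from the standard elliptic-integral expressions
    (Smythe-type) together with dK/dm and dE/dm, and are exact up to
    rounding; they were cross-checked against central finite differences.
    """
    C = ampere_turns / (2.0 * math.pi)
    m = 4.0 * a * rho / ((a + rho) ** 2 + z**2)
    Kv = ellipk(m)
    Ev = ellipe(m)

    x0 = a**2
    x1 = z**2
    x2 = rho**2
    x3 = x1 + x2
    x4 = x0 + x3
    x5 = a - rho
    x6 = x5**2
    x7 = x1 + x6
    x8 = -Kv * x7
    x9 = Ev * x4 + x8
    x10 = 1.0 / rho
    x11 = a + rho
    x12 = x1 + x11**2
    x13 = C / (np.sqrt(x12) * x7)
    x14 = -x0 + x3
    x15 = Ev * x14 + x8
    x16 = 4.0 * rho
    x17 = -a * x16 + x12
    x18 = rho * x7
    x19 = Ev - Kv
    x20 = 2.0 * x11
    x21 = -rho * x20 + x12
    x22 = x7**2
    x23 = Ev * x12
    x24 = x22 * (-Kv * x17 + x23)
    x25 = x21 * x24
    x26 = x17 * x18 * x20
    x27 = x17 * x7
    x28 = x12 * x27 * x9
    x29 = C / (x12**1.5 * x17 * x22)
    x30 = x29 * z
    x31 = x17 * x23
    x32 = 2.0 * x31
    x33 = x10 * x29
    x34 = x14 * x19

    Hr = x10 * x13 * x9 * z
    Hz = -x13 * x15
    dHr_drho = 0.5 * x30 * (
        4.0 * Ev * rho * x12 * x17 * (x18 + x4 * x5)
        + x17 * x19 * x21 * x4 * x7 - x25 - x26 * x9 - 2.0 * x28
    ) / x2
    dHr_dz = -x33 * (
        -x1 * x24 + x1 * x27 * (x19 * x4 + x9)
        + x1 * x32 * (x0 + x2 - x6) - x28
    )
    dHz_drho = -0.5 * x33 * (
        -x15 * x26 + x16 * x31 * (x14 * x5 + x18) + x21 * x27 * x34 - x25
    )
    dHz_dz = -x30 * (x24 - x27 * (x15 + x34) + x32 * (x0 - x2 + x6))
    return Hr, Hz, dHr_drho, dHr_dz, dHz_drho, dHz_dz


def _loop_axis(ampere_turns: float, a: float, z: np.ndarray):
    """On-axis closed form: H_z = N I a^2 / (2 (a^2 + z^2)^(3/2))."""
    s = a**2 + z**2
    Hz = ampere_turns * a**2 / (2.0 * s**1.5)
    dHz_dz = -3.0 * ampere_turns * a**2 * z / (2.0 * s**2.5)
    return Hz, dHz_dz


def coil_field_many(coil: CoilSpec, current: float, points: np.ndarray):
    """Vectorized loop field at many points.

    Parameters
    ----------
    points : (n, 3) array of cartesian positions, m.

    Returns
    -------
    H : (n, 3) array, A/m.
    J : (n, 3, 3) array, ``J[p, i, j] = dH_i/dx_j``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not (np.all(np.isfinite(points)) and np.isfinite(current)):
        raise ValueError("non-finite input to coil_field")
    n = points.shape[0]
    H = np.zeros((n, 3))
    J = np.zeros((n, 3, 3))
    if current == 0.0:
        return H, J

    zhat = coil.axis
    d = points - coil.center
    z = d @ zhat
    rvec = d - np.outer(z, zhat)
    rho = np.linalg.norm(rvec, axis=1)

    # singularity guard: distance to the filament circle
    filament_dist = np.hypot(rho - coil.radius, z)
    if np.any(filament_dist <= _FILAMENT_TOL):
        raise ValueError("field evaluation point lies on the coil filament")

    ampere_turns = coil.turns * current
    on_axis = rho < _AXIS_TOL
    off = ~on_axis

    eye = np.eye(3)
    if np.any(off):
        ro = rho[off]
        zo = z[off]
        Hr, Hz, drr, drz, dzr, dzz = _loop_cyl(ampere_turns, coil.radius, ro, zo)
        rhat = rvec[off] / ro[:, None]
        H[off] = Hr[:, None] * rhat + Hz[:, None] * zhat
        # J = drr r r' + drz r z' + dzr z r' + dzz z z' + (Hr/rho)(I - zz' - rr')
        rr = rhat[:, :, None] * rhat[:, None, :]
        zz = np.outer(zhat, zhat)
        rz = rhat[:, :, None] * zhat[None, None, :]
        zr = zhat[None, :, None] * rhat[:, None, :]
        J[off] = (
            drr[:, None, None] * rr
            + drz[:, None, None] * rz
            + dzr[:, None, None] * zr
            + dzz[:, None, None] * zz
            + (Hr / ro)[:, None, None] * (eye - zz - rr)
        )
    if np.any(on_axis):
        Hz, dzz = _loop_axis(ampere_turns, coil.radius, z[on_axis])
        H[on_axis] = Hz[:, None] * zhat
        zz = np.outer(zhat, zhat)
        # divergence-free axisymmetric limit: dHr/drho -> -dHz/dz / 2
        J[on_axis] = dzz[:, None, None] * zz \
            + (-0.5 * dzz)[:, None, None] * (eye - zz)
    return H, J


def coil_field(coil: CoilSpec, current: float, point) -> FieldSample:
    """Field and Jacobian of one coil at a single point."""
    H, J = coil_field_many(coil, current, np.asarray(point, dtype=float).reshape(1, 3))
    return FieldSample(H=H[0], jacobian=J[0])


def total_field_arrays(coils, currents, points):
    """Superposed field of all coils at many points (array form)."""
    currents = np.asarray(currents, dtype=float).reshape(-1)
    if len(currents) != len(coils):
        raise ValueError(
            f"{len(coils)} coils but {len(currents)} currents"
        )
    points = np.atleast_2d(np.asarray(points, dtype=float))
    H = np.zeros((points.shape[0], 3))
    J = np.zeros((points.shape[0], 3, 3))
    for coil, current in zip(coils, currents):
        Hc, Jc = coil_field_many(coil, current, points)
        H += Hc
        J += Jc
    return H, J


def total_field(coils, currents, points) -> list[FieldSample]:
    """Superposed field of all coils at each point, as FieldSamples."""
    H, J = total_field_arrays(coils, currents, points)
    return [FieldSample(H=H[i], jacobian=J[i]) for i in range(H.shape[0])]


# ---------------------------------------------------------------------------
# magnetization and force
# ---------------------------------------------------------------------------

def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x.

    Odd, bounded by 1 in magnitude, with L(x) ~ x/3 for small x.  A Taylor
    branch x/3 - x^3/45 is used for |x| < 1e-4 to avoid catastrophic
    cancellation between coth(x) and 1/x.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _LANGEVIN_SMALL
    xs = np.where(small, 1.0, x)  # avoid 1/0 in the dead branch
    out = np.where(small, x / 3.0 - x**3 / 45.0, 1.0 / np.tanh(xs) - 1.0 / xs)
    if out.ndim == 0:
        return float(out)
    return out


def _langevin_argument(H_mag, particle: ParticleSpec):
    return (MU0 * particle.saturation_magnetization * particle.core_volume
            / (KB * particle.temperature)) * np.asarray(H_mag, dtype=float)


def magnetization(H_mag, particle: ParticleSpec):
    """Equilibrium magnetization M(H) = Ms L(mu0 Ms V H / (kB T)), A/m."""
    return particle.saturation_magnetization * langevin(_langevin_argument(H_mag, particle))


def moment_coefficient(H_mag, particle: ParticleSpec):
    """g(H) with particle moment m = g(H) H, units m^3.

    g(H) = V M(H) / H for H > 0; the H -> 0 limit is the initial
    susceptibility form g(0) = mu0 Ms^2 V^2 / (3 kB T), so g is continuous.
    """
    H_mag = np.asarray(H_mag, dtype=float)
    V = particle.core_volume
    Ms = particle.saturation_magnetization
    g0 = MU0 * Ms**2 * V**2 / (3.0 * KB * particle.temperature)
    Hs = np.where(H_mag > 0, H_mag, 1.0)
    g = np.where(H_mag > 0, V * magnetization(Hs, particle) / Hs, g0)
    if g.ndim == 0:
        return float(g)
    return g


def magnetic_force(sample: FieldSample, particle: ParticleSpec) -> np.ndarray:
    """Point-dipole force F = (m . grad) B = mu0 g(|H|) (dH/dx)^T H, N.

    For the curl-free coil field this equals (mu0/2) g(|H|) grad(H^2).
    """
    H = sample.H
    Hmag = float(np.linalg.norm(H))
    if Hmag == 0.0:
        return np.zeros_like(H)
    g = moment_coefficient(Hmag, particle)
    return MU0 * g * (sample.jacobian.T @ H)


def magnetic_force_many(H: np.ndarray, J: np.ndarray, particle: ParticleSpec) -> np.ndarray:
    """Vectorized force for (n,3) fields and (n,3,3) Jacobians."""
    Hmag = np.linalg.norm(H, axis=1)
    g = moment_coefficient(Hmag, particle)
    JtH = np.einsum("nji,nj->ni", J, H)
    return MU0 * g[:, None] * JtH


def drift_velocity(force, viscosity: float, hydrodynamic_radius: float, flow=0.0):
    """Inertialess particle velocity v = F / (6 pi eta R_p) + v_f, m/s."""
    if not viscosity > 0:
        raise ValueError("viscosity must be positive")
    if not hydrodynamic_radius > 0:
        raise ValueError("hydrodynamic radius must be positive")
    zeta = 6.0 * math.pi * viscosity * hydrodynamic_radius
    return np.asarray(force, dtype=float) / zeta + np.asarray(flow, dtype=float)
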