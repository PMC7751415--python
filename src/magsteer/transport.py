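"""Voxel discretization of the advection-diffusion equation.

The sample is a 2-D grid of square voxels of side ``dx``; each voxel holds
one dimensionless concentration, flattened with index ``k = i + nx * j``
(0-based, ``i`` along x).  A finite-volume discretization of

    dc/dt = div(D grad c) - div(v c),        n . (D grad c - v c) = 0 on walls

yields the linear state-space system ``cdot = A(u) c``.  Every interior
face carries the flux ``-D (c_R - c_L)/dx + v_face (c_L + c_R)/2`` (central
scheme; a first-order upwind advective flux is available for
advection-dominated cases), which enters the two adjacent voxel balances
with opposite signs; boundary faces carry no flux, so every column of A
sums to zero and the total particle mass is conserved exactly.

In the interior with uniform velocity this finite-volume form coincides
with the classical second-order central-difference stencils.  Time
integration is classical fixed-step RK4, with the sub-step chosen from the
diffusive and advective stability limits of the assembled operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import magnetics
from .magnetics import ParticleSpec, magnetic_force_many

__all__ = [
    "Grid2D",
    "FluidSpec",
    "DriftField",
    "ConcentrationField",
    "TransportOperator",
    "Trajectory",
    "FaceFieldCache",
    "drift_field",
    "assemble_operator",
    "integrate",
    "rk4_integrate",
    "summarize",
]

#: safety factor on the explicit RK4 stability sub-step
_CFL_SAFETY = 0.4
#: norm-growth factor that triggers the instability diagnostic
_BLOWUP_FACTOR = 1e6


@dataclass(frozen=True)
class Grid2D:
    """Uniform 2-D voxel grid in the z = 0 plane.

    ``origin`` is the lower-left corner of the sample; voxel centers sit at
    ``origin + ((i + 1/2) dx, (j + 1/2) dx)``.
    """

    nx: int
    ny: int
    dx: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one voxel per axis")
        if not self.dx > 0:
            raise ValueError("dx must be positive")
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(2))

    @classmethod
    def centered(cls, side_x: float, side_y: float, nx: int, ny: int) -> "Grid2D":
        """Grid for a sample of the given side lengths centered at the origin."""
        dx = side_x / nx
        if abs(side_y / ny - dx) > 1e-12 * dx:
            raise ValueError("voxels must be square: side_x/nx != side_y/ny")
        return cls(nx=nx, ny=ny, dx=dx, origin=np.array([-side_x / 2, -side_y / 2]))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def index(self, i: int, j: int) -> int:
        """Flattened voxel index k = i + nx * j."""
        return i + self.nx * j

    @property
    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) voxel-center coordinates in flattening order."""
        i = np.arange(self.nx)
        j = np.arange(self.ny)
        xc = self.origin[0] + (i + 0.5) * self.dx
        yc = self.origin[1] + (j + 0.5) * self.dx
        X, Y = np.meshgrid(xc, yc, indexing="xy")  # row j, col i
        return np.column_stack([X.ravel(), Y.ravel()])

    def face_centers_x(self) -> np.ndarray:
        """Centers of interior faces normal to x, ((nx-1)*ny, 2).

        Ordered with i fastest: face f = i + (nx-1) * j separates voxels
        (i, j) and (i+1, j).
        """
        i = np.arange(self.nx - 1)
        j = np.arange(self.ny)
        xf = self.origin[0] + (i + 1.0) * self.dx
        yf = self.origin[1] + (j + 0.5) * self.dx
        X, Y = np.meshgrid(xf, yf, indexing="xy")
        return np.column_stack([X.ravel(), Y.ravel()])

    def face_centers_y(self) -> np.ndarray:
        """Centers of interior faces normal to y, (nx*(ny-1), 2)."""
        i = np.arange(self.nx)
        j = np.arange(self.ny - 1)
        xf = self.origin[0] + (i + 0.5) * self.dx
        yf = self.origin[1] + (j + 1.0) * self.dx
        X, Y = np.meshgrid(xf, yf, indexing="xy")
        return np.column_stack([X.ravel(), Y.ravel()])

    def voxel_at(self, point) -> int:
        """Flattened index of the voxel containing ``point``."""
        p = np.asarray(point, dtype=float).reshape(2)
        ij = np.floor((p - self.origin) / self.dx).astype(int)
        ij = np.clip(ij, [0, 0], [self.nx - 1, self.ny - 1])
        return self.index(int(ij[0]), int(ij[1]))


@dataclass(frozen=True)
class FluidSpec:
    """Carrier-fluid parameters.

    ``flow`` is either a uniform (2,) velocity or a per-voxel (n_cells, 2)
    field; ``diffusion`` is the particle diffusion coefficient D in m^2/s.
    """

    viscosity: float
    diffusion: float
    flow: np.ndarray

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion coefficient must be nonnegative")
        flow = np.asarray(self.flow, dtype=float)
        if not np.all(np.isfinite(flow)):
            raise ValueError("flow field must be finite")
        object.__setattr__(self, "flow", flow)

    def flow_at(self, points: np.ndarray, grid: Grid2D | None = None) -> np.ndarray:
        """Flow velocity sampled at arbitrary points.

        Uniform flow broadcasts; a per-voxel field is interpolated with
        nearest-voxel lookup (adequate for the slowly varying flows used
        here).
        """
        points = np.atleast_2d(points)
        if self.flow.ndim == 1:
            return np.broadcast_to(self.flow, (points.shape[0], 2)).copy()
        if grid is None:
            raise ValueError("grid required to sample a per-voxel flow field")
        idx = [grid.voxel_at(p) for p in points]
        return self.flow[idx]


@dataclass(frozen=True)
class ConcentrationField:
    """Dimensionless per-voxel particle concentration."""

    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float).reshape(-1)
        if not np.all(np.isfinite(c)):
            raise ValueError("concentration field must be finite")
        object.__setattr__(self, "c", c)

    @property
    def total_mass(self) -> float:
        return float(self.c.sum())


@dataclass(frozen=True)
class DriftField:
    """Total particle velocity (magnetic drift + flow) at interior faces.

    ``vx`` holds the x-velocity at x-normal faces, ``vy`` the y-velocity at
    y-normal faces, both in the face orderings of :class:`Grid2D`.
    ``drag`` caches zeta = 6 pi eta R_p.
    """

    vx: np.ndarray
    vy: np.ndarray
    drag: float


@dataclass(frozen=True)
class TransportOperator:
    """Sparse state matrix A (1/s) with the currents it was assembled for."""

    A: sp.csr_matrix
    currents: np.ndarray


@dataclass(frozen=True)
class Trajectory:
    """Snapshots of the concentration state on a uniform time grid.

    ``states`` has shape (n_cells, n_snapshots): column s is c(times[s]).
    """

    times: np.ndarray
    states: np.ndarray


class FaceFieldCache:
    """Unit-current field and Jacobian of each coil at all interior faces.

    The coil field is linear in the current, so the per-coil responses are
    computed once per (grid, coils) pair and superposed per current vector;
    the force is then evaluated nonlinearly through g(|H|).
    """

    def __init__(self, grid: Grid2D, coils) -> None:
        self.grid = grid
        self.coils = tuple(coils)
        fx = grid.face_centers_x()
        fy = grid.face_centers_y()
        pts = np.vstack([fx, fy])
        pts3 = np.column_stack([pts, np.zeros(len(pts))])
        self.n_fx = len(fx)
        self._H_unit = np.empty((len(self.coils), len(pts), 3))
        self._J_unit = np.empty((len(self.coils), len(pts), 3, 3))
        for c, coil in enumerate(self.coils):
            H, J = magnetics.coil_field_many(coil, 1.0, pts3)
            self._H_unit[c] = H
            self._J_unit[c] = J

    def field(self, currents: np.ndarray):
        """Superposed H and Jacobian at all faces for a current vector."""
        currents = np.asarray(currents, dtype=float).reshape(-1)
        if len(currents) != len(self.coils):
            raise ValueError("currents length does not match coils")
        H = np.tensordot(currents, self._H_unit, axes=(0, 0))
        J = np.tensordot(currents, self._J_unit, axes=(0, 0))
        return H, J


def drift_field(grid: Grid2D, coils, currents, particle: ParticleSpec,
                fluid: FluidSpec, cache: FaceFieldCache | None = None) -> DriftField:
    """Total face-centered particle velocity for a current vector.

    The magnetic drift is evaluated directly at face midpoints (the flux
    quadrature points); out-of-plane force components are discarded for the
    planar model.
    """
    if cache is None:
        cache = FaceFieldCache(grid, coils)
    currents = np.asarray(currents, dtype=float).reshape(-1)
    drag = 6.0 * np.pi * fluid.viscosity * particle.hydrodynamic_radius
    H, J = cache.field(currents)
    F = magnetic_force_many(H, J, particle)
    v_mag = F[:, :2] / drag
    fx = grid.face_centers_x()
    fy = grid.face_centers_y()
    flow_x = fluid.flow_at(fx, grid)[:, 0]
    flow_y = fluid.flow_at(fy, grid)[:, 1]
    n_fx = cache.n_fx
    vx = v_mag[:n_fx, 0] + flow_x
    vy = v_mag[n_fx:, 1] + flow_y
    if not (np.all(np.isfinite(vx)) and np.all(np.isfinite(vy))):
        raise ValueError("non-finite drift velocity")
    return DriftField(vx=vx, vy=vy, drag=drag)


def assemble_operator(grid: Grid2D, drift: DriftField, diffusion: float,
                      scheme: str = "central") -> TransportOperator:
    """Assemble the sparse transport matrix A from face velocities.

    ``scheme`` selects the advective face value: "central" uses the
    arithmetic mean (c_L + c_R)/2, "upwind" the donor cell.
    """
    if scheme not in ("central", "upwind"):
        raise ValueError(f"unknown scheme {scheme!r}")
    nx, ny, dx = grid.nx, grid.ny, grid.dx
    n = grid.n_cells
    if len(drift.vx) != (nx - 1) * ny or len(drift.vy) != nx * (ny - 1):
        raise ValueError("drift field does not match grid faces")
    if not (np.all(np.isfinite(drift.vx)) and np.all(np.isfinite(drift.vy))):
        raise ValueError("non-finite drift field")

    rows = []
    cols = []
    vals = []

    def add_faces(left: np.ndarray, right: np.ndarray, v: np.ndarray) -> None:
        # flux through the face (positive from left to right), per unit dx:
        #   F = -D (c_R - c_L)/dx + v * c_face
        # contributes -F/dx to d c_L/dt and +F/dx to d c_R/dt.
        dif = diffusion / dx
        if scheme == "central":
            a_L = v / 2.0 + dif   # coefficient of c_L in F
            a_R = v / 2.0 - dif   # coefficient of c_R in F
        else:  # upwind
            a_L = np.where(v > 0, v, 0.0) + dif
            a_R = np.where(v > 0, 0.0, v) - dif
        rows.extend([left, left, right, right])
        cols.extend([left, right, left, right])
        vals.extend([-a_L / dx, -a_R / dx, a_L / dx, a_R / dx])

    # x-normal faces: left voxel (i, j), right voxel (i+1, j)
    i = np.arange(nx - 1)
    j = np.arange(ny)
    I, Jj = np.meshgrid(i, j, indexing="xy")
    left = (I + nx * Jj).ravel()
    add_faces(left, left + 1, drift.vx)

    # y-normal faces: left voxel (i, j), right voxel (i, j+1)
    i = np.arange(nx)
    j = np.arange(ny - 1)
    I, Jj = np.meshgrid(i, j, indexing="xy")
    left = (I + nx * Jj).ravel()
    add_faces(left, left + nx, drift.vy)

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    A.sum_duplicates()
    return TransportOperator(A=A, currents=np.array([]))


def stable_substep(grid: Grid2D, drift: DriftField, diffusion: float) -> float:
    """RK4 sub-step from diffusive and advective stability limits.

    dt = safety * min(dx^2 / (4 D), dx / max |v|); infinite when the
    operator is identically zero (any step is exact then).
    """
    limits = []
    if diffusion > 0:
        limits.append(grid.dx**2 / (4.0 * diffusion))
    vmax = max(np.abs(drift.vx).max(initial=0.0), np.abs(drift.vy).max(initial=0.0))
    if vmax > 0:
        limits.append(grid.dx / vmax)
    if not limits:
        return np.inf
    return _CFL_SAFETY * min(limits)


def rk4_integrate(A, c0: np.ndarray, duration: float, n_steps: int) -> np.ndarray:
    """Advance cdot = A c over ``duration`` with ``n_steps`` fixed RK4 steps."""
    c = np.asarray(c0, dtype=float).copy()
    if duration == 0.0 or n_steps == 0:
        return c
    h = duration / n_steps
    norm0 = np.linalg.norm(c)
    for _ in range(n_steps):
        k1 = A @ c
        k2 = A @ (c + 0.5 * h * k1)
        k3 = A @ (c + 0.5 * h * k2)
        k4 = A @ (c + h * k3)
        c = c + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if norm0 > 0 and np.linalg.norm(c) > _BLOWUP_FACTOR * norm0:
        raise RuntimeError(
            "time integration unstable (state norm grew by more than "
            f"{_BLOWUP_FACTOR:g}); reduce the RK4 sub-step (h = {h:g} s)"
        )
    return c


def _segment_steps(duration: float, dt: float) -> int:
    if duration <= 0:
        return 0
    if not np.isfinite(dt):
        return 1
    return max(1, int(np.ceil(duration / dt)))


def integrate(c0, schedule, grid: Grid2D, coils, particle: ParticleSpec,
              fluid: FluidSpec, n_snapshots: int = 101, scheme: str = "central",
              cache: FaceFieldCache | None = None) -> Trajectory:
    """Integrate the full-order model under a piecewise-constant schedule.

    Within each constant-current segment the operator A(u) is assembled
    once and advanced with fixed RK4 sub-steps.  Snapshots are returned on
    a uniform grid over [0, t_f] including both endpoints.
    """
    c0 = np.asarray(getattr(c0, "c", c0), dtype=float).reshape(-1)
    if c0.size != grid.n_cells:
        raise ValueError("initial state does not match grid")
    if n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    if cache is None:
        cache = FaceFieldCache(grid, coils)

    t_f = schedule.t_f
    snap_times = np.linspace(0.0, t_f, n_snapshots)
    states = np.empty((grid.n_cells, n_snapshots))
    states[:, 0] = c0

    c = c0.copy()
    s = 1
    for t0, t1, u in schedule.segments():
        drift = drift_field(grid, coils, u, particle, fluid, cache=cache)
        op = assemble_operator(grid, drift, fluid.diffusion, scheme=scheme)
        dt = stable_substep(grid, drift, fluid.diffusion)
        t = t0
        while s < n_snapshots and snap_times[s] <= t1 + 1e-9 * t_f:
            target = min(snap_times[s], t1)
            c = rk4_integrate(op.A, c, target - t, _segment_steps(target - t, dt))
            t = target
            states[:, s] = c
            s += 1
        if t < t1:
            c = rk4_integrate(op.A, c, t1 - t, _segment_steps(t1 - t, dt))
    return Trajectory(times=snap_times, states=states)


def summarize(c, grid: Grid2D, targets=()) -> dict:
    """Concentration metrics: target values, mass centroid, RMS spread."""
    c = np.asarray(getattr(c, "c", c), dtype=float).reshape(-1)
    mass = c.sum()
    if mass <= 0:
        raise ValueError("cannot summarize a zero- or negative-mass field")
    centers = grid.cell_centers
    centroid = (c @ centers) / mass
    # tiny negative voxel values from the central scheme can push the second
    # moment marginally below zero for near-singular fields; clamp at 0
    second = (c @ np.sum((centers - centroid) ** 2, axis=1)) / mass
    spread = float(np.sqrt(max(second, 0.0)))
    targets = np.asarray(list(targets), dtype=int)
    return {
        "target_concentration": c[targets] if targets.size else np.array([]),
        "centroid": centroid,
        "spread": spread,
        "total_mass": float(mass),
    }
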