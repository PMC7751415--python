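"""Proper orthogonal decomposition and Galerkin projection of the dynamics.

A snapshot matrix X collects full-order states at sample times.  Its SVD
X = U S V' yields an energy-optimal orthonormal basis; the retained rank l
is the smallest one whose captured energy fraction

    eps(l) = sum_{i<=l} sigma_i^2 / sum_{i<=d} sigma_i^2

reaches a target (or l is fixed directly).  Snapshots are used raw, without
mean-centering.  The reduced system is the Galerkin projection
x ~ U_l xt, d xt/dt = U_l' A(u) U_l xt, with the quadratic state cost
projected as Qt = U_l' Q U_l and path constraints evaluated on the lifted
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .transport import Trajectory

__all__ = [
    "SnapshotMatrix",
    "PODBasis",
    "ReducedModel",
    "compute_pod",
    "project_model",
    "reduced_integrate",
]


@dataclass(frozen=True)
class SnapshotMatrix:
    """States at snapshot times, one column per snapshot."""

    X: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[1] < 2:
            raise ValueError("need at least 2 snapshots")
        if not np.all(np.isfinite(X)):
            raise ValueError("snapshots must be finite")
        object.__setattr__(self, "X", X)

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "SnapshotMatrix":
        return cls(X=traj.states, times=traj.times)


@dataclass(frozen=True)
class PODBasis:
    """Leading left singular vectors of a snapshot matrix.

    ``U`` has orthonormal columns (rank l), ``singular_values`` holds all d
    singular values, and ``energy`` is eps(l).
    """

    U: np.ndarray
    singular_values: np.ndarray
    rank: int
    energy: float

    def energy_fraction(self, l: int) -> float:
        """eps(l) for any retained rank l."""
        s2 = self.singular_values**2
        return float(s2[:l].sum() / s2.sum())


def compute_pod(X, energy_target: float | None = 0.98,
                rank: int | None = None) -> PODBasis:
    """POD basis of a snapshot matrix by SVD.

    ``rank`` fixes l directly, bypassing the energy criterion; otherwise l
    is the smallest integer with eps(l) >= energy_target.  Columns follow a
    deterministic sign convention: the largest-magnitude entry of each mode
    is positive.
    """
    X = np.atleast_2d(np.asarray(getattr(X, "X", X), dtype=float))
    if not np.any(X):
        raise ValueError("snapshot matrix is identically zero")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    # numerical rank d: drop trailing zero singular values
    d = int(np.count_nonzero(s > s[0] * np.finfo(float).eps * max(X.shape)))
    s = s[:d]
    U = U[:, :d]
    if rank is not None:
        if not 1 <= rank <= d:
            raise ValueError(f"rank must be in [1, {d}]")
        l = int(rank)
    else:
        if energy_target is None or not 0.0 < energy_target <= 1.0:
            raise ValueError("energy_target must lie in (0, 1]")
        frac = np.cumsum(s**2) / np.sum(s**2)
        l = int(np.searchsorted(frac, energy_target - 1e-15) + 1)
        l = min(l, d)
    Ul = U[:, :l].copy()
    # sign convention
    lead = np.abs(Ul).argmax(axis=0)
    signs = np.sign(Ul[lead, np.arange(l)])
    signs[signs == 0] = 1.0
    Ul *= signs
    s2 = s**2
    return PODBasis(U=Ul, singular_values=s, rank=l,
                    energy=float(s2[:l].sum() / s2.sum()))


@dataclass(frozen=True)
class ReducedModel:
    """Galerkin-projected dynamics, cost and constraints.

    ``a_builder(u)`` returns the full-order (sparse) operator for a current
    vector; ``assemble(u)`` projects it to l x l.  ``q_diag`` is the
    diagonal of the full-order state cost Q.
    """

    U: np.ndarray
    a_builder: Callable[[np.ndarray], sp.spmatrix]
    q_diag: np.ndarray | None = None
    state_bounds: tuple | None = None  # (indices, lower, upper) on lifted state

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if np.linalg.norm(U.T @ U - np.eye(U.shape[1])) > 1e-10:
            raise ValueError("basis columns must be orthonormal")
        object.__setattr__(self, "U", U)
        if self.q_diag is not None:
            object.__setattr__(self, "q_diag",
                               np.asarray(self.q_diag, dtype=float).reshape(-1))

    @property
    def order(self) -> int:
        return self.U.shape[1]

    def restrict(self, x: np.ndarray) -> np.ndarray:
        """xt = U' x."""
        return self.U.T @ x

    def lift(self, xt: np.ndarray) -> np.ndarray:
        """x ~ U xt."""
        return self.U @ xt

    def assemble(self, u) -> np.ndarray:
        """Reduced operator At(u) = U' A(u) U (dense l x l)."""
        A = self.a_builder(np.asarray(u, dtype=float))
        return np.asarray(self.U.T @ (A @ self.U))

    @property
    def q_reduced(self) -> np.ndarray:
        """Qt = U' Q U for diagonal Q."""
        if self.q_diag is None:
            raise ValueError("model has no state cost")
        return self.U.T @ (self.q_diag[:, None] * self.U)

    def path_constraint(self, xt: np.ndarray):
        """Residuals of lifted-state bounds (>= 0 feasible); None if unset."""
        if self.state_bounds is None:
            return None
        idx, lower, upper = self.state_bounds
        x = self.lift(xt)[idx]
        res = []
        if lower is not None:
            res.append(x - lower)
        if upper is not None:
            res.append(upper - x)
        return np.concatenate(res)


def project_model(a_builder, q_diag, U, state_bounds=None) -> ReducedModel:
    """Build a :class:`ReducedModel` from a full-order operator builder."""
    return ReducedModel(U=np.asarray(U, dtype=float), a_builder=a_builder,
                        q_diag=q_diag, state_bounds=state_bounds)


def reduced_integrate(x0t, schedule, model: ReducedModel,
                      n_snapshots: int = 101,
                      substep: float | Callable[[np.ndarray], float] | None = None,
                      ) -> Trajectory:
    """Integrate the reduced system under a piecewise-constant schedule.

    Same RK4 contract as :func:`magsteer.transport.integrate`, with the
    l-dimensional state.  ``substep`` is either a fixed sub-step, a callable
    u -> dt (e.g. the full-order stability rule), or None for a spectral
    estimate from the reduced operator itself.
    """
    from .transport import rk4_integrate, _segment_steps  # shared RK4 core

    x = np.asarray(x0t, dtype=float).reshape(-1)
    t_f = schedule.t_f
    snap_times = np.linspace(0.0, t_f, n_snapshots)
    states = np.empty((x.size, n_snapshots))
    states[:, 0] = x

    s = 1
    for t0, t1, u in schedule.segments():
        At = model.assemble(u)
        if callable(substep):
            dt = substep(u)
        elif substep is not None:
            dt = float(substep)
        else:
            lam = np.abs(np.linalg.eigvals(At)).max()
            dt = np.inf if lam == 0 else 1.0 / lam
        t = t0
        while s < n_snapshots and snap_times[s] <= t1 + 1e-9 * t_f:
            target = min(snap_times[s], t1)
            x = rk4_integrate(At, x, target - t, _segment_steps(target - t, dt))
            t = target
            states[:, s] = x
            s += 1
        if t < t1:
            x = rk4_integrate(At, x, t1 - t, _segment_steps(t1 - t, dt))
    return Trajectory(times=snap_times, states=states)
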