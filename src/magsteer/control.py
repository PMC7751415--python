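"""Optimal control of electromagnet currents by direct multiple shooting.

The control signal is a zero-order-hold current vector: each of the n_t
segments of the horizon [0, t_f] carries one constant current per coil,
bounded elementwise by |u| <= u_max.  The running cost is quadratic,

    J = int_0^tf ( x' Q x + u' R u ) dt + gamma t_f,

with Q diagonal: -w at voxels whose concentration is maximized, +w at
voxels to avoid, 0 elsewhere (t_f is held fixed here, gamma merely offsets
the reported cost).

The transcription is direct multiple shooting: the decision variables are
the n_t current vectors together with the reduced states at the n_t - 1
interior shooting nodes; each segment is integrated by RK4 in the
POD-reduced space, equality constraints stitch the segments together, and
the resulting NLP is solved with a gradient-based SQP method using forward
finite differences.  An outer loop alternates full-order simulation, POD
basis refresh and reduced-space optimization, keeping the best full-order
solution found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .reduction import ReducedModel, SnapshotMatrix, compute_pod, project_model
from .transport import Grid2D, Trajectory, _segment_steps, rk4_integrate

logger = logging.getLogger(__name__)

__all__ = [
    "CurrentSchedule",
    "OCProblem",
    "OCSolution",
    "build_cost",
    "evaluate_cost",
    "initial_guess",
    "dms_solve",
    "alternating_pod_dms",
]

#: snapshots per shooting segment used for the quadrature of the running cost
_SEGMENT_SAMPLES = 26
#: feasibility slack on the current bounds accepted from the NLP solver
_BOUND_TOL = 1e-8


@dataclass(frozen=True)
class CurrentSchedule:
    """Zero-order-hold currents: u[:, k] is applied on segment k.

    Segment boundaries are t_k = k t_f / n_t.
    """

    u: np.ndarray
    t_f: float

    def __post_init__(self) -> None:
        u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if not self.t_f > 0:
            raise ValueError("t_f must be positive")
        if u.shape[1] < 1:
            raise ValueError("need at least one segment")
        object.__setattr__(self, "u", u)

    @property
    def n_u(self) -> int:
        return self.u.shape[0]

    @property
    def n_t(self) -> int:
        return self.u.shape[1]

    @property
    def boundaries(self) -> np.ndarray:
        return np.linspace(0.0, self.t_f, self.n_t + 1)

    def segments(self):
        """Yield (t_start, t_end, current vector) per segment."""
        b = self.boundaries
        for k in range(self.n_t):
            yield b[k], b[k + 1], self.u[:, k]

    def current_at(self, t: float) -> np.ndarray:
        k = min(int(t / self.t_f * self.n_t), self.n_t - 1)
        return self.u[:, k]


@dataclass
class OCProblem:
    """Targeting optimal-control problem over a fixed horizon.

    ``a_builder(u)`` returns the full-order transport operator for a
    current vector; ``simulate_full(schedule, n_snapshots)`` integrates the
    full-order model from ``x0``.  ``substep_rule(u)``, if given, supplies
    the RK4 sub-step used in the reduced space (normally the full-order
    stability rule, which bounds the projected spectrum in practice).
    """

    x0: np.ndarray
    q_diag: np.ndarray
    r_diag: np.ndarray
    gamma: float
    t_f: float
    u_max: float
    n_t: int
    n_u: int
    targets: tuple = ()
    a_builder: Callable | None = None
    simulate_full: Callable | None = None
    substep_rule: Callable | None = None
    state_bounds: tuple | None = None
    n_snapshots: int = 101

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float).reshape(-1)
        self.q_diag = np.asarray(self.q_diag, dtype=float).reshape(-1)
        self.r_diag = np.asarray(self.r_diag, dtype=float).reshape(-1)
        if not self.t_f > 0:
            raise ValueError("t_f must be positive")
        if not self.u_max > 0:
            raise ValueError("u_max must be positive")


@dataclass
class OCSolution:
    """Optimized schedule with full-order re-evaluation and history."""

    schedule: CurrentSchedule
    cost: float
    trajectory: Trajectory | None = None
    reduced_cost: float | None = None
    history: list = field(default_factory=list)
    status: str = "ok"
    n_iterations: int = 0


def build_cost(n_states: int, targets, weights=1.0, avoid=(), avoid_weights=1.0,
               r_diag=None, n_u: int = 0, gamma: float = 0.0):
    """Diagonal cost matrices for a targeting problem.

    Target voxels get -weight on the Q diagonal (their squared
    concentration is maximized), avoid voxels +weight, all others zero.
    """
    q = np.zeros(n_states)
    targets = np.atleast_1d(np.asarray(targets, dtype=int))
    if np.any((targets < 0) | (targets >= n_states)):
        raise IndexError("target voxel index out of range")
    q[targets] = -np.broadcast_to(np.asarray(weights, dtype=float), targets.shape)
    if len(avoid):
        avoid = np.atleast_1d(np.asarray(avoid, dtype=int))
        if np.any((avoid < 0) | (avoid >= n_states)):
            raise IndexError("avoid voxel index out of range")
        q[avoid] = np.broadcast_to(np.asarray(avoid_weights, dtype=float), avoid.shape)
    r = np.zeros(n_u) if r_diag is None else np.asarray(r_diag, dtype=float).reshape(-1)
    return q, r, float(gamma)


def _control_energy(schedule: CurrentSchedule, r_diag: np.ndarray) -> float:
    """Exact integral of u' R u for a zero-order-hold schedule."""
    if r_diag.size == 0 or not np.any(r_diag):
        return 0.0
    seg = schedule.t_f / schedule.n_t
    return float(seg * np.sum(r_diag[:, None] * schedule.u**2))


def evaluate_cost(trajectory: Trajectory, schedule: CurrentSchedule,
                  q_diag: np.ndarray, r_diag: np.ndarray, gamma: float) -> float:
    """Quadrature of the quadratic running cost along a trajectory.

    The state term is integrated by the trapezoidal rule on the snapshot
    grid; the control term is piecewise constant and integrated exactly;
    gamma contributes gamma * t_f.
    """
    times = trajectory.times
    X = trajectory.states
    if X.shape[1] != times.size:
        raise ValueError("trajectory snapshots do not match time grid")
    lx = np.einsum("is,i,is->s", X, q_diag, X)
    J = float(np.trapezoid(lx, times))
    J += _control_energy(schedule, r_diag)
    J += gamma * schedule.t_f
    return J


def initial_guess(problem: OCProblem, grid: Grid2D, coils,
                  fraction: float = 1.0, flow=None) -> CurrentSchedule:
    """Alignment heuristic for the starting currents.

    Each coil is driven in proportion to the positive cosine between the
    direction from the initial centroid to that coil and the desired
    direction of motion (centroid -> target), scaled so the best-aligned
    coil carries ``fraction * u_max``.  For a holding problem (target at
    the centroid) the desired direction opposes the flow; with no flow the
    guess is all-zero.  The single-coil force is even in its current, so
    positive currents are used throughout.
    """
    mass = problem.x0.sum()
    if mass <= 0:
        raise ValueError("initial state must have positive mass")
    centers = grid.cell_centers
    centroid = (problem.x0 @ centers) / mass
    if len(problem.targets):
        target_pos = centers[np.asarray(problem.targets, dtype=int)].mean(axis=0)
    else:
        target_pos = centroid
    d = target_pos - centroid
    if np.linalg.norm(d) < grid.dx / 2:
        flow = np.zeros(2) if flow is None else np.asarray(flow, dtype=float).reshape(-1)[:2]
        if np.linalg.norm(flow) == 0:
            return CurrentSchedule(u=np.zeros((problem.n_u, problem.n_t)),
                                   t_f=problem.t_f)
        d = -flow
    d = d / np.linalg.norm(d)
    align = np.zeros(problem.n_u)
    for c, coil in enumerate(coils):
        to_coil = np.asarray(coil.center, dtype=float)[:2] - centroid
        n = np.linalg.norm(to_coil)
        if n > 0:
            align[c] = max(0.0, float(to_coil @ d) / n)
    if align.max() > 0:
        align = align / align.max()
    u0 = fraction * problem.u_max * align
    return CurrentSchedule(u=np.tile(u0[:, None], (1, problem.n_t)), t_f=problem.t_f)


# ---------------------------------------------------------------------------
# direct multiple shooting
# ---------------------------------------------------------------------------

class _Shooter:
    """Per-segment reduced integration with memoization.

    The SQP finite-difference loop perturbs one decision variable at a
    time, so caching each segment's result on (segment currents, node
    state) avoids re-integrating unaffected segments.
    """

    def __init__(self, problem: OCProblem, model: ReducedModel):
        self.problem = problem
        self.model = model
        self.seg_duration = problem.t_f / problem.n_t
        self.qt = model.q_reduced if model.q_diag is not None else None
        self._op_cache: dict[bytes, tuple[np.ndarray, float]] = {}
        self._seg_cache: dict[tuple, tuple[np.ndarray, float]] = {}

    def _operator(self, u: np.ndarray):
        key = u.tobytes()
        hit = self._op_cache.get(key)
        if hit is None:
            At = self.model.assemble(u)
            if self.problem.substep_rule is not None:
                dt = self.problem.substep_rule(u)
            else:
                lam = np.abs(np.linalg.eigvals(At)).max()
                dt = np.inf if lam == 0 else 1.0 / lam
            hit = (At, dt)
            self._op_cache[key] = hit
        return hit

    def segment(self, u: np.ndarray, x0t: np.ndarray):
        """Integrate one segment; returns (end state, segment state-cost)."""
        key = (u.tobytes(), x0t.tobytes())
        hit = self._seg_cache.get(key)
        if hit is not None:
            return hit
        At, dt = self._operator(u)
        tau = self.seg_duration
        times = np.linspace(0.0, tau, _SEGMENT_SAMPLES)
        x = x0t.copy()
        states = np.empty((x.size, _SEGMENT_SAMPLES))
        states[:, 0] = x
        for s in range(1, _SEGMENT_SAMPLES):
            h = times[s] - times[s - 1]
            x = rk4_integrate(At, x, h, _segment_steps(h, dt))
            states[:, s] = x
        if self.qt is None:
            cost = 0.0
        else:
            lx = np.einsum("is,ij,js->s", states, self.qt, states)
            cost = float(np.trapezoid(lx, times))
        hit = (x, cost)
        self._seg_cache[key] = hit
        return hit

    def shoot(self, u_all: np.ndarray, nodes: np.ndarray):
        """All segments: total reduced cost and node continuity defects."""
        problem = self.problem
        l = self.model.order
        x0t = self.model.restrict(problem.x0)
        defects = np.empty((problem.n_t - 1) * l) if problem.n_t > 1 else np.empty(0)
        cost = 0.0
        x = x0t
        for k in range(problem.n_t):
            end, seg_cost = self.segment(np.ascontiguousarray(u_all[:, k]), x)
            cost += seg_cost
            if k < problem.n_t - 1:
                nxt = nodes[k * l:(k + 1) * l]
                defects[k * l:(k + 1) * l] = end - nxt
                x = nxt
        return cost, defects

    def sequential_cost(self, schedule: CurrentSchedule) -> float:
        """Reduced cost of a schedule by single shooting from x0."""
        x = self.model.restrict(self.problem.x0)
        cost = 0.0
        for _, _, u in schedule.segments():
            x, seg_cost = self.segment(np.ascontiguousarray(u), x)
            cost += seg_cost
        return cost


def _full_cost(problem: OCProblem, schedule: CurrentSchedule):
    """Re-evaluate a schedule on the full-order model, if available."""
    if problem.simulate_full is None:
        return None, None
    traj = problem.simulate_full(schedule, problem.n_snapshots)
    J = evaluate_cost(traj, schedule, problem.q_diag, problem.r_diag, problem.gamma)
    return J, traj


def dms_solve(problem: OCProblem, model: ReducedModel, guess: CurrentSchedule,
              max_iter: int = 100, warm_nodes: np.ndarray | None = None) -> OCSolution:
    """Solve the reduced-space OCP by direct multiple shooting.

    Decision variables: the n_t current vectors (scaled by u_max) and the
    reduced states at interior shooting nodes (scaled by the initial state
    magnitude).  Node continuity is enforced as equality constraints;
    |u| <= u_max as box bounds; optional lifted-state concentration bounds
    as inequality constraints at the nodes.  Solved with SLSQP and forward
    finite differences of relative step 1e-3.
    """
    if np.abs(guess.u).max() > problem.u_max + _BOUND_TOL:
        raise ValueError("initial guess violates the current bounds")
    shooter = _Shooter(problem, model)
    l = model.order
    n_u, n_t = problem.n_u, problem.n_t

    if max_iter == 0:
        red = shooter.sequential_cost(guess) + _control_energy(guess, problem.r_diag) \
            + problem.gamma * problem.t_f
        J_full, traj = _full_cost(problem, guess)
        return OCSolution(schedule=guess, cost=J_full if J_full is not None else red,
                          trajectory=traj, reduced_cost=red, status="guess",
                          n_iterations=0)

    x_scale = max(float(np.abs(model.restrict(problem.x0)).max()), 1e-12)
    seg = problem.t_f / n_t

    # warm-start node states: propagate the guess unless provided
    if warm_nodes is None:
        nodes = np.empty((n_t - 1) * l)
        x = model.restrict(problem.x0)
        for k in range(n_t - 1):
            x, _ = shooter.segment(np.ascontiguousarray(guess.u[:, k]), x)
            nodes[k * l:(k + 1) * l] = x
    else:
        nodes = np.asarray(warm_nodes, dtype=float).reshape((n_t - 1) * l)

    z0 = np.concatenate([guess.u.ravel() / problem.u_max, nodes / x_scale])

    def unpack(z):
        u_all = z[:n_u * n_t].reshape(n_u, n_t) * problem.u_max
        nd = z[n_u * n_t:] * x_scale
        return u_all, nd

    def control_energy(u_all):
        if not np.any(problem.r_diag):
            return 0.0
        return float(seg * np.sum(problem.r_diag[:, None] * u_all**2))

    cost_scale = 1.0 / problem.t_f  # keep the objective O(state^2)

    def objective(z):
        u_all, nd = unpack(z)
        cost, _ = shooter.shoot(u_all, nd)
        return (cost + control_energy(u_all) + problem.gamma * problem.t_f) * cost_scale

    def defects(z):
        u_all, nd = unpack(z)
        _, d = shooter.shoot(u_all, nd)
        return d / x_scale

    constraints = []
    if n_t > 1:
        constraints.append({"type": "eq", "fun": defects})
    if model.state_bounds is not None and n_t > 1:
        def state_ineq(z):
            _, nd = unpack(z)
            return np.concatenate([
                model.path_constraint(nd[k * l:(k + 1) * l])
                for k in range(n_t - 1)
            ])
        constraints.append({"type": "ineq", "fun": state_ineq})

    bounds = [(-1.0, 1.0)] * (n_u * n_t) + [(None, None)] * ((n_t - 1) * l)
    res = minimize(objective, z0, method="SLSQP", bounds=bounds,
                   constraints=constraints,
                   options={"maxiter": max_iter, "ftol": 1e-10, "eps": 1e-3})

    u_opt, _ = unpack(res.x)
    u_opt = np.clip(u_opt, -problem.u_max, problem.u_max)
    candidate = CurrentSchedule(u=u_opt, t_f=problem.t_f)

    # best feasible iterate: compare candidate and guess by sequential
    # reduced cost (defect-free by construction)
    red_candidate = shooter.sequential_cost(candidate) + control_energy(candidate.u) \
        + problem.gamma * problem.t_f
    red_guess = shooter.sequential_cost(guess) + control_energy(guess.u) \
        + problem.gamma * problem.t_f
    status = "converged" if res.success else f"nlp: {res.message}"
    if red_candidate <= red_guess:
        best, red_best = candidate, red_candidate
    else:
        best, red_best = guess, red_guess
        status += " (guess retained)"
        logger.info("DMS iterate worse than guess; returning guess")

    J_full, traj = _full_cost(problem, best)
    return OCSolution(schedule=best,
                      cost=J_full if J_full is not None else red_best,
                      trajectory=traj, reduced_cost=red_best,
                      history=[{"reduced_cost": red_best, "nlp_status": res.message}],
                      status=status, n_iterations=int(res.nit))


def alternating_pod_dms(problem: OCProblem, n_opt: int = 2,
                        energy_target: float | None = 0.98,
                        rank: int | None = None,
                        stop_threshold: float | None = None,
                        guess: CurrentSchedule | None = None,
                        max_iter: int = 100,
                        max_outer: int | None = None) -> OCSolution:
    """Alternate POD basis refresh and reduced-space DMS.

    The loop (i) simulates the full-order model under the current best
    schedule, (ii) computes a POD basis from those snapshots, (iii) runs
    DMS in the reduced space warm-started from the previous currents and
    node states restricted under the new basis, and (iv) re-applies the
    optimized currents to the full-order model.  The best full-order
    solution seen is kept, so the reported cost is nonincreasing.
    """
    if problem.simulate_full is None or problem.a_builder is None:
        raise ValueError("problem must carry simulate_full and a_builder")
    if n_opt < 1 and stop_threshold is None:
        raise ValueError("need n_opt >= 1 or a stop threshold")
    if max_outer is None:
        max_outer = n_opt + 10 if stop_threshold is not None else n_opt
    if guess is None:
        raise ValueError("an initial guess schedule is required")

    schedule = guess
    traj = problem.simulate_full(schedule, problem.n_snapshots)
    J = evaluate_cost(traj, schedule, problem.q_diag, problem.r_diag, problem.gamma)
    best = OCSolution(schedule=schedule, cost=J, trajectory=traj,
                      status="guess", history=[])
    history = [{"iteration": 0, "cost": J, "rank": None,
                "u": schedule.u.copy(), "role": "initial guess"}]

    node_times = np.linspace(0.0, problem.t_f, problem.n_t + 1)[1:-1]

    def target_concentration(trajectory: Trajectory) -> float:
        if not len(problem.targets):
            return np.inf
        return float(trajectory.states[list(problem.targets), -1].sum())

    i = 0
    while i < max_outer:
        if i >= n_opt and not (
            stop_threshold is not None
            and target_concentration(best.trajectory) < stop_threshold
        ):
            break
        basis = compute_pod(SnapshotMatrix.from_trajectory(traj),
                            energy_target=energy_target, rank=rank)
        model = project_model(problem.a_builder, problem.q_diag, basis.U,
                              state_bounds=problem.state_bounds)
        # warm start: previous currents + restriction of the previous
        # full-order node states under the NEW basis
        if problem.n_t > 1:
            idx = np.array([int(np.argmin(np.abs(traj.times - t))) for t in node_times])
            warm = np.concatenate([basis.U.T @ traj.states[:, s] for s in idx])
        else:
            warm = None
        sol = dms_solve(problem, model, schedule, max_iter=max_iter, warm_nodes=warm)
        schedule = sol.schedule
        traj = sol.trajectory
        J = sol.cost
        history.append({"iteration": i + 1, "cost": J, "rank": basis.rank,
                        "u": schedule.u.copy(), "role": "dms",
                        "reduced_cost": sol.reduced_cost,
                        "pod_energy": basis.energy, "status": sol.status})
        logger.info("outer iteration %d: rank=%d, J=%.6g", i + 1, basis.rank, J)
        if J <= best.cost:
            best = OCSolution(schedule=schedule, cost=J, trajectory=traj,
                              reduced_cost=sol.reduced_cost, status=sol.status)
        i += 1

    best.history = history
    best.n_iterations = i
    return best
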