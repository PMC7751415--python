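"""Scenario configuration, synthetic inputs, file I/O and end-to-end runs.

A scenario bundles everything the pipeline needs: sample and grid
geometry, the four-coil arrangement, particle and fluid parameters, the
control horizon and bounds, the POD settings, the initial particle blob
and the target voxel.  Configurations round-trip losslessly through a
YAML file with SI units throughout.

The packaged reference scenario reproduces the published study
conditions where they are printed (8 cm x 8 cm sample, 31 x 31 voxels,
400 nm magnetite particles with Ms = 4.78e5 A/m, u_max = 13 A,
t_f = 10000 s, n_t = 4, POD energy threshold 0.98); quantities the study
leaves open (coil winding count and standoff, blob position and extent,
diffusion coefficient) carry documented defaults -- see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control, transport
from .control import CurrentSchedule, OCProblem
from .magnetics import CoilSpec, ParticleSpec
from .transport import FaceFieldCache, FluidSpec, Grid2D, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "default_setup",
    "ci_setup",
    "make_initial_blob",
    "make_uniform_flow",
    "build_coils",
    "build_scenario",
    "run_scenario",
    "write_trajectory",
    "read_trajectory",
    "write_schedule",
    "read_schedule",
]


@dataclass
class ScenarioConfig:
    """Complete, serializable description of one targeting run (SI units)."""

    # sample and grid
    sample_side_x: float = 0.08        # m
    sample_side_y: float = 0.08        # m
    nx: int = 31
    ny: int = 31
    # coils: symmetric ring of up to 4 in the sample plane (0 = pure simulation)
    n_coils: int = 4
    coil_radius: float = 0.05          # m
    coil_turns: int = 10000
    coil_standoff: float = 0.10        # m, coil center to sample center
    # particle
    core_diameter: float = 400e-9      # m
    saturation_magnetization: float = 4.78e5   # A/m
    temperature: float = 300.0         # K
    hydrodynamic_radius: float | None = None   # m; None -> core radius
    # fluid
    viscosity: float = 3e-3            # Pa s (blood-like)
    diffusion: float | None = None     # m^2/s; None -> Stokes-Einstein
    flow: tuple[float, float] = (0.0, 0.0)     # m/s, uniform
    # control
    u_max: float = 13.0                # A
    t_f: float = 10000.0               # s
    n_t: int = 4
    guess_fraction: float = 1.0        # of u_max for the best-aligned coil
    max_nlp_iter: int = 60
    # reduction
    energy_target: float | None = 0.98
    pod_rank: int | None = None
    n_opt: int = 2
    n_snapshots: int = 101
    # initial distribution and target
    blob_center: tuple[float, float] = (-0.03, 0.0)   # m
    blob_sigma: float = 0.0025                         # m
    blob_mass: float = 1.0
    target_point: tuple[float, float] = (0.0, 0.01)    # m
    # numerics
    scheme: str = "central"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("flow", "blob_center", "target_point"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("flow", "blob_center", "target_point"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_setup() -> ScenarioConfig:
    """Reference steering scenario: stationary fluid, printed target."""
    return ScenarioConfig()


def ci_setup() -> ScenarioConfig:
    """Scaled-down scenario for fast tests: coarser grid, shorter horizon."""
    return ScenarioConfig(
        nx=15, ny=15, n_t=2, t_f=4000.0, n_snapshots=41,
        blob_sigma=0.005, target_point=(-0.01, 0.01),
        max_nlp_iter=30, n_opt=1,
    )


def make_initial_blob(grid: Grid2D, center, sigma: float, total_mass: float = 1.0
                      ) -> np.ndarray:
    """Isotropic Gaussian sampled at voxel centers, normalized to total_mass.

    A sigma below dx/10 degenerates to a single-voxel spike at the nearest
    voxel center.
    """
    center = np.asarray(center, dtype=float).reshape(2)
    lo = grid.origin
    hi = grid.origin + np.array([grid.nx, grid.ny]) * grid.dx
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError(f"blob center {center.tolist()} outside the sample")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    c = np.zeros(grid.n_cells)
    if sigma <= grid.dx / 10:
        c[grid.voxel_at(center)] = total_mass
        return c
    r2 = np.sum((grid.cell_centers - center) ** 2, axis=1)
    c = np.exp(-r2 / (2.0 * sigma**2))
    return c * (total_mass / c.sum())


def make_uniform_flow(vx: float, vy: float) -> np.ndarray:
    """Constant flow field (m/s); (0, 0) is the stationary-fluid case."""
    flow = np.array([float(vx), float(vy)])
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow must be finite")
    return flow


def build_coils(config: ScenarioConfig) -> list[CoilSpec]:
    """Four coils on the +-x and +-y axes, axes pointing at the sample center."""
    s = config.coil_standoff
    placements = [((s, 0, 0), (-1, 0, 0)), ((0, s, 0), (0, -1, 0)),
                  ((-s, 0, 0), (1, 0, 0)), ((0, -s, 0), (0, 1, 0))]
    if not 0 <= config.n_coils <= 4:
        raise ValueError("n_coils must be between 0 and 4")
    return [CoilSpec(center=np.array(c, dtype=float), axis=np.array(a, dtype=float),
                     radius=config.coil_radius, turns=config.coil_turns)
            for c, a in placements[:config.n_coils]]


@dataclass
class Scenario:
    """Fully constructed run-time objects for one configuration."""

    config: ScenarioConfig
    grid: Grid2D
    coils: list[CoilSpec]
    particle: ParticleSpec
    fluid: FluidSpec
    cache: FaceFieldCache
    problem: OCProblem
    target_voxel: int


def stokes_einstein_diffusion(particle: ParticleSpec, viscosity: float) -> float:
    """D = kB T / (6 pi eta R_p)."""
    from .magnetics import KB
    return KB * particle.temperature / (
        6.0 * np.pi * viscosity * particle.hydrodynamic_radius)


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Instantiate grid, coils, particle, fluid and the OC problem."""
    grid = Grid2D.centered(config.sample_side_x, config.sample_side_y,
                           config.nx, config.ny)
    coils = build_coils(config)
    particle = ParticleSpec(
        core_diameter=config.core_diameter,
        saturation_magnetization=config.saturation_magnetization,
        temperature=config.temperature,
        hydrodynamic_radius=config.hydrodynamic_radius,
    )
    diffusion = config.diffusion
    if diffusion is None:
        diffusion = stokes_einstein_diffusion(particle, config.viscosity)
    fluid = FluidSpec(viscosity=config.viscosity, diffusion=diffusion,
                      flow=np.asarray(config.flow, dtype=float))
    cache = FaceFieldCache(grid, coils)
    x0 = make_initial_blob(grid, config.blob_center, config.blob_sigma,
                           config.blob_mass)
    target_voxel = grid.voxel_at(config.target_point)
    q, r, gamma = control.build_cost(grid.n_cells, [target_voxel],
                                     n_u=len(coils), gamma=0.0)

    def a_builder(u):
        drift = transport.drift_field(grid, coils, u, particle, fluid, cache=cache)
        return transport.assemble_operator(grid, drift, fluid.diffusion,
                                           scheme=config.scheme).A

    def substep_rule(u):
        drift = transport.drift_field(grid, coils, u, particle, fluid, cache=cache)
        return transport.stable_substep(grid, drift, fluid.diffusion)

    def simulate_full(schedule, n_snapshots):
        return transport.integrate(x0, schedule, grid, coils, particle, fluid,
                                   n_snapshots=n_snapshots, scheme=config.scheme,
                                   cache=cache)

    problem = OCProblem(
        x0=x0, q_diag=q, r_diag=r, gamma=gamma, t_f=config.t_f,
        u_max=config.u_max, n_t=config.n_t, n_u=len(coils),
        targets=(target_voxel,), a_builder=a_builder,
        simulate_full=simulate_full, substep_rule=substep_rule,
        n_snapshots=config.n_snapshots,
    )
    return Scenario(config=config, grid=grid, coils=coils, particle=particle,
                    fluid=fluid, cache=cache, problem=problem,
                    target_voxel=target_voxel)


# ---------------------------------------------------------------------------
# tabular I/O (delimited text, documented headers)
# ---------------------------------------------------------------------------

def write_trajectory(path, traj: Trajectory) -> None:
    """One row per snapshot: time_s then the concentrations in k = i + nx*j order."""
    n = traj.states.shape[0]
    df = pd.DataFrame(traj.states.T, columns=[f"c{k}" for k in range(n)])
    df.insert(0, "time_s", traj.times)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(times=df["time_s"].to_numpy(),
                      states=df.drop(columns="time_s").to_numpy().T)


def write_schedule(path, schedule: CurrentSchedule) -> None:
    """One row per segment: start time then one current column per coil (A)."""
    df = pd.DataFrame(schedule.u.T,
                      columns=[f"coil{c}_A" for c in range(schedule.n_u)])
    df.insert(0, "t_start_s", schedule.boundaries[:-1])
    df.to_csv(path, index=False, float_format="%.17g")


def read_schedule(path, t_f: float) -> CurrentSchedule:
    df = pd.read_csv(path)
    return CurrentSchedule(u=df.drop(columns="t_start_s").to_numpy().T, t_f=t_f)


def write_metrics(path, traj: Trajectory, grid: Grid2D, targets) -> None:
    rows = []
    for s, t in enumerate(traj.times):
        m = transport.summarize(traj.states[:, s], grid, targets)
        rows.append({
            "time_s": t,
            "target_concentration": float(m["target_concentration"].sum()),
            "centroid_x_m": m["centroid"][0],
            "centroid_y_m": m["centroid"][1],
            "spread_m": m["spread"],
            "total_mass": m["total_mass"],
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def run_scenario(config: ScenarioConfig, outdir, seed: int | None = None):
    """Execute the alternating POD-DMS pipeline and write all artifacts.

    The pipeline is deterministic; ``seed`` is accepted for interface
    uniformity and seeds NumPy in case stochastic extensions are enabled.
    Returns the :class:`magsteer.control.OCSolution`.
    """
    if seed is not None:
        np.random.seed(seed % 2**31)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scn = build_scenario(config)
    problem = scn.problem
    if len(scn.coils) == 0:
        # no actuation: degenerate to a pure transport simulation
        schedule = CurrentSchedule(u=np.zeros((0, config.n_t)), t_f=config.t_f)
        traj = problem.simulate_full(schedule, config.n_snapshots)
        J = control.evaluate_cost(traj, schedule, problem.q_diag,
                                  problem.r_diag, problem.gamma)
        sol = control.OCSolution(schedule=schedule, cost=J, trajectory=traj,
                                 status="simulation only",
                                 history=[{"iteration": 0, "cost": J,
                                           "rank": None, "u": schedule.u,
                                           "role": "simulation"}])
    else:
        guess = control.initial_guess(problem, scn.grid, scn.coils,
                                      fraction=config.guess_fraction,
                                      flow=np.asarray(config.flow, dtype=float))
        sol = control.alternating_pod_dms(
            problem, n_opt=config.n_opt, energy_target=config.energy_target,
            rank=config.pod_rank, guess=guess, max_iter=config.max_nlp_iter,
        )
    config.save(outdir / "config.yaml")
    write_trajectory(outdir / "trajectory.csv", sol.trajectory)
    write_schedule(outdir / "schedule.csv", sol.schedule)
    write_metrics(outdir / "metrics.csv", sol.trajectory, scn.grid,
                  [scn.target_voxel])
    hist = [{k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in h.items()} for h in sol.history]
    (outdir / "history.json").write_text(json.dumps({
        "cost": sol.cost, "status": sol.status,
        "n_iterations": sol.n_iterations, "history": hist,
    }, indent=2))
    logger.info("scenario finished: J = %.6g, status = %s", sol.cost, sol.status)
    return sol
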