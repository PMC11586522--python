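"""Immersed-boundary coupling of the spring-network tissue to Stokes flow.

Each time step runs the classic five-step loop:

1. forces at the solid nodes (elastic + active contractile tension),
2. *spreading* of node forces onto the fluid grid through a smoothed delta
   kernel,
3. a Stokes solve for the fluid velocity,
4. *interpolation* of fluid velocities back to the solid nodes with the
   adjoint of the spreading kernel,
5. forward-Euler advection of the nodes.

Spreading and interpolation share the 4-point Peskin kernel, so they form a
dual pair: total spread force equals total solid force exactly, a uniform
velocity field interpolates exactly (partition of unity), and the power
exchanged by the two operators matches.

Because the Stokes problem is linear and the domain static, rescaling the
viscosity by 1/c together with the ramp time and duration by 1/c yields the
identical trajectory on a rescaled clock; ``run_simulation`` preserves this
exactly by taking its step count from ``dt`` and the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EmbryoGeometry, polygon_area
from .mechanics import ForceProtocol, total_forces
from .stokes import FluidDomain, VelocityField, solve_stokes

__all__ = [
    "SimulationParams",
    "SimulationState",
    "Trajectory",
    "peskin_delta_4pt",
    "spread_forces",
    "interpolate_velocities",
    "step",
    "run_simulation",
    "compartment_volumes",
    "reynolds_number",
]


def peskin_delta_4pt(r: np.ndarray) -> np.ndarray:
    """Peskin's 4-point smoothed delta kernel φ(r), supported on |r| < 2.

    Satisfies Σ_j φ(r − j) = 1 and Σ_j (r − j) φ(r − j) = 0 for all r, which
    gives exact force conservation and linear-field reproduction.
    """
    r = np.abs(np.asarray(r, float))
    out = np.zeros_like(r)
    near = r < 1.0
    mid = (r >= 1.0) & (r < 2.0)
    rn = r[near]
    out[near] = (3.0 - 2.0 * rn + np.sqrt(1.0 + 4.0 * rn - 4.0 * rn * rn)) / 8.0
    rm = r[mid]
    out[mid] = (5.0 - 2.0 * rm - np.sqrt(-7.0 + 12.0 * rm - 4.0 * rm * rm)) / 8.0
    return out


def _kernel_weights(domain: FluidDomain, positions: np.ndarray, a: int):
    """Indices and weights of the 4^dim kernel support on the a-face lattice.

    Returns flat face indices (N, 4^dim) and weights (N, 4^dim), built as an
    outer product of per-axis 4-point stencils.  Raises if a node's kernel
    support leaves the grid.
    """
    origin = domain.face_origin(a)
    fshape = domain.face_shape(a)
    g = (positions - origin) / domain.h  # fractional lattice coordinates
    base = np.floor(g).astype(int)

    idx1d = []
    w1d = []
    for c in range(domain.dim):
        ic = base[:, c, None] + np.arange(-1, 3)  # (N, 4)
        if ic[:, 0].min() < 0 or ic[:, -1].max() >= fshape[c]:
            raise ValueError("solid node kernel support extends outside the fluid grid")
        idx1d.append(ic)
        w1d.append(peskin_delta_4pt(g[:, c, None] - ic))

    n = len(positions)
    if domain.dim == 2:
        flat = (idx1d[0][:, :, None] * fshape[1] + idx1d[1][:, None, :]).reshape(n, 16)
        w = (w1d[0][:, :, None] * w1d[1][:, None, :]).reshape(n, 16)
    else:
        flat = (
            (idx1d[0][:, :, None, None] * fshape[1] + idx1d[1][:, None, :, None])
            * fshape[2]
            + idx1d[2][:, None, None, :]
        ).reshape(n, 64)
        w = (
            w1d[0][:, :, None, None]
            * w1d[1][:, None, :, None]
            * w1d[2][:, None, None, :]
        ).reshape(n, 64)
    return flat, w


def _weights_all(domain: FluidDomain, positions: np.ndarray):
    return [_kernel_weights(domain, positions, a) for a in range(domain.dim)]


def spread_forces(
    solid_forces: np.ndarray,
    positions: np.ndarray,
    domain: FluidDomain,
    weights=None,
) -> tuple[np.ndarray, ...]:
    """Spread node forces to the grid as a force density (IBM step 2).

    Each component is deposited on its own staggered face lattice with
    weight φ(Δx/h)·φ(Δy/h)[·φ(Δz/h)] / h^dim, so that
    Σ_faces f · h^dim = Σ_nodes F exactly.
    """
    solid_forces = np.asarray(solid_forces, float)
    if weights is None:
        weights = _weights_all(domain, positions)
    out = []
    inv_vol = 1.0 / domain.cell_measure
    for a in range(domain.dim):
        flat, w = weights[a]
        vals = np.bincount(
            flat.ravel(),
            weights=(w * solid_forces[:, a, None]).ravel() * inv_vol,
            minlength=int(np.prod(domain.face_shape(a))),
        )
        out.append(vals.reshape(domain.face_shape(a)))
    return tuple(out)


def interpolate_velocities(
    vel: VelocityField,
    positions: np.ndarray,
    domain: FluidDomain,
    weights=None,
) -> np.ndarray:
    """Interpolate grid velocities to solid nodes (IBM step 4) using the
    same kernel weights as spreading (adjoint pair)."""
    out = np.zeros_like(np.asarray(positions, float))
    if weights is None:
        weights = _weights_all(domain, positions)
    for a in range(domain.dim):
        flat, w = weights[a]
        out[:, a] = np.sum(w * vel.components[a].ravel()[flat], axis=1)
    return out


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationParams:
    """Time-stepping and stopping control.

    ``dt`` is the explicit Euler step; it must respect the spring relaxation
    stability bound (roughly dt ≲ c·η·ℓ0/K_m for the stiffest spring).
    ``stop_window_frac``/``stop_depth_frac`` implement the plateau rule: stop
    once the running maximum furrow depth has not grown by more than
    ``stop_depth_frac`` × vitelline radius over the trailing
    ``stop_window_frac`` fraction of elapsed time.  ``min_time`` guards the
    rule against firing before forces have built up.
    """

    dt: float
    t_max: float
    sample_every: int = 10
    stop_window_frac: float = 0.05
    stop_depth_frac: float = 0.001
    min_time: float = 0.0
    density: float = 1e3  # kg/m^3, Reynolds diagnostic only

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max < self.dt:
            raise ValueError("t_max must allow at least one step")


@dataclass
class SimulationState:
    """Instantaneous simulation state: time, node positions, the most recent
    fluid velocity field and per-compartment measures."""

    t: float
    positions: np.ndarray
    velocity: VelocityField | None = None
    volumes: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Sampled time course of a simulation.

    ``positions`` is (n_samples, N, dim); ``volumes`` maps compartment name →
    per-sample measures.  ``depth`` is the furrow-depth series measured
    during the run.  ``flow`` holds the final sampled velocity field.
    """

    times: np.ndarray
    positions: np.ndarray
    volumes: dict
    depth: np.ndarray
    geometry: EmbryoGeometry
    domain: FluidDomain
    protocol: ForceProtocol
    params: SimulationParams
    flow: VelocityField | None = None
    stopped_on_plateau: bool = False

    def final_state(self) -> SimulationState:
        return SimulationState(
            t=float(self.times[-1]),
            positions=self.positions[-1],
            velocity=self.flow,
            volumes={k: v[-1] for k, v in self.volumes.items()},
        )


def compartment_volumes(state: SimulationState, geometry: EmbryoGeometry) -> dict:
    """Per-compartment measures (areas in 2D).

    Closed geometry: every cell polygon, the yolk, and the perivitelline
    space (vitelline disk minus the embryo's outer boundary polygon).  Open
    geometry: the merged yolk∪cells compartment plus each cell's *retained*
    area — its open polygon closed by the straight basal chord.
    """
    pos = state.positions
    if geometry.dim == 3:
        from .geometry import cell_volume_3d

        vols = np.array(
            [
                cell_volume_3d(pos, geometry.faces[c.face_ids()])
                for c in geometry.cells3d
                if c.basal_faces is not None
            ]
        )
        return {"cells": vols}
    out = {}
    cell_areas = np.array(
        [polygon_area(pos[c.polygon()]) for c in geometry.cells]
    )
    if np.any(cell_areas <= 0):
        raise ValueError("non-positive cell area: boundary self-intersection?")
    outer = polygon_area(pos[geometry.outer_boundary_loop()])
    total = np.pi * geometry.vitelline_radius**2
    out["cells"] = cell_areas
    out["perivitelline"] = total - outer
    if geometry.basal_open:
        out["yolk_and_cells"] = outer
        out["retained"] = cell_areas
    else:
        out["yolk"] = polygon_area(pos[geometry.yolk_polygon()])
    return out


def reynolds_number(rho: float, v: float, L: float, eta: float) -> float:
    """Re = ρ v L / η (SI inputs), the inertia/viscosity ratio — of order
    1e−8 for gastrulation flows, justifying the Stokes limit."""
    if rho < 0 or v < 0 or L < 0 or eta <= 0:
        raise ValueError("require non-negative rho, v, L and positive eta")
    return rho * v * L / eta


def step(
    state: SimulationState,
    geometry: EmbryoGeometry,
    protocol: ForceProtocol,
    params: SimulationParams,
    domain: FluidDomain,
) -> SimulationState:
    """Advance one time step through the five IBM stages."""
    F = total_forces(geometry, protocol, state.t, state.positions)
    weights = _weights_all(domain, state.positions)
    f = spread_forces(F, state.positions, domain, weights)
    vel = solve_stokes(domain, f)
    V = interpolate_velocities(vel, state.positions, domain, weights)
    new_pos = state.positions + params.dt * V
    if not np.all(np.isfinite(new_pos)):
        raise FloatingPointError(
            f"non-finite node positions at t={state.t:.4g}; "
            "dt likely exceeds the spring stability limit"
        )
    return SimulationState(t=state.t + params.dt, positions=new_pos, velocity=vel)


def run_simulation(
    geometry: EmbryoGeometry,
    protocol: ForceProtocol,
    params: SimulationParams,
    domain: FluidDomain,
    depth_fn=None,
) -> Trajectory:
    """Iterate the IBM loop until the furrow-depth plateau rule fires or
    ``t_max`` is reached, sampling states every ``sample_every`` steps.

    ``depth_fn(positions) -> float`` defaults to the inward radial
    displacement of the midline apical node(s).
    """
    from .morphometrics import furrow_depth  # local import to avoid a cycle

    if depth_fn is None:
        ref = geometry.nodes
        def depth_fn(pos):
            return furrow_depth(SimulationState(t=0.0, positions=pos), geometry,
                                reference=ref)

    state = SimulationState(t=0.0, positions=geometry.nodes.copy())
    times = [0.0]
    samples = [state.positions.copy()]
    depths = [depth_fn(state.positions)]
    vols = [compartment_volumes(state, geometry)]
    stopped = False

    n_steps = int(np.ceil(params.t_max / params.dt))
    R = geometry.vitelline_radius
    run_max = [(0.0, depths[0])]  # (t, running max depth)

    last_vel = None
    for k in range(n_steps):
        state = step(state, geometry, protocol, params, domain)
        last_vel = state.velocity
        if (k + 1) % params.sample_every == 0 or k == n_steps - 1:
            d = depth_fn(state.positions)
            times.append(state.t)
            samples.append(state.positions.copy())
            depths.append(d)
            vols.append(compartment_volumes(state, geometry))

            prev_max = run_max[-1][1]
            run_max.append((state.t, max(prev_max, d)))
            if state.t >= max(params.min_time, params.dt):
                window = params.stop_window_frac * state.t
                t_then = state.t - window
                # running max as of the start of the trailing window
                past = [m for tt, m in run_max if tt <= t_then]
                if past and run_max[-1][1] - past[-1] < params.stop_depth_frac * R:
                    stopped = True
                    break

    vol_keys = vols[0].keys()
    volumes = {k: np.asarray([v[k] for v in vols]) for k in vol_keys}
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(samples),
        volumes=volumes,
        depth=np.asarray(depths),
        geometry=geometry,
        domain=domain,
        protocol=protocol,
        params=params,
        flow=last_vel,
        stopped_on_plateau=stopped,
    )
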