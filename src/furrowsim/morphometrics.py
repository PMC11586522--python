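"""Measurements on simulated embryos, mirroring how fixed embryos are scored:
furrow depth, time to maximal invagination, lateral membrane-length profiles,
flow recirculation, and the depth-versus-ramp-time scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EmbryoGeometry
from .ibm import SimulationParams, SimulationState, Trajectory, run_simulation
from .mechanics import ForceProtocol
from .stokes import FluidDomain, VelocityField

__all__ = [
    "furrow_depth",
    "time_to_max_depth",
    "lateral_length_profile",
    "flow_recirculation",
    "ramp_scan",
    "RampScanResult",
]


def furrow_depth(
    state: SimulationState,
    geometry: EmbryoGeometry,
    reference: np.ndarray | None = None,
) -> float:
    """Inward radial displacement (µm) of the ventral-midline apical surface.

    Measured as the mean over the geometry's midline apical node(s), relative
    to their initial radial position.  Positive = inward (invagination).
    """
    ids = geometry.midline_apical_nodes
    if len(ids) == 0:
        raise ValueError("geometry defines no midline apical nodes")
    ref = geometry.nodes if reference is None else reference
    r0 = np.linalg.norm(ref[ids], axis=1)
    r1 = np.linalg.norm(state.positions[ids], axis=1)
    return float(np.mean(r0 - r1))


def time_to_max_depth(traj: Trajectory) -> tuple[float, bool]:
    """Earliest sample time at which the depth series attains its maximum.

    Returns ``(t, plateaued)``; ``plateaued`` is False when the depth was
    still rising at the end of the run (the maximum sits on the last sample
    and the stop rule never fired), in which case ``t`` is a lower bound.
    """
    if len(traj.times) < 2:
        raise ValueError("trajectory needs at least two samples")
    i = int(np.argmax(traj.depth))
    plateaued = traj.stopped_on_plateau or i < len(traj.depth) - 1
    return float(traj.times[i]), plateaued


def lateral_length_profile(
    state: SimulationState,
    geometry: EmbryoGeometry,
    positions_range: tuple[int, int] = (-10, 9),
) -> pd.DataFrame:
    """Arc length of each lateral membrane, indexed by its signed position
    (number of cells between the membrane and the ventral midline).

    Returns a DataFrame with columns ``position`` and ``length_um``.
    Membranes missing from the geometry are skipped.
    """
    lo, hi = positions_range
    pos = state.positions
    rows = []
    for s in range(lo, hi + 1):
        edge_ids = geometry.laterals.get(s)
        if edge_ids is None or len(edge_ids) == 0:
            continue
        e = geometry.edges[edge_ids]
        seg = np.linalg.norm(pos[e[:, 1]] - pos[e[:, 0]], axis=1)
        rows.append({"position": s, "length_um": float(seg.sum())})
    return pd.DataFrame(rows)


def flow_recirculation(
    state: SimulationState,
    domain: FluidDomain,
    noise_floor_frac: float = 0.01,
) -> tuple[float, float, bool]:
    """Signed circulation (vorticity integral) over the left and right
    interior half-domains, split at the midline vertical.

    Returns ``(left, right, recirculating)`` where ``recirculating`` is True
    when the two halves carry opposite signs and both exceed the noise floor
    (``noise_floor_frac`` × max |circulation|).
    """
    if state.velocity is None:
        raise ValueError("state carries no cached velocity field")
    vel: VelocityField = state.velocity
    if domain.dim != 2:
        raise NotImplementedError("recirculation measure is 2D")
    h = domain.h
    u, v = vel.u, vel.v
    # vorticity dv/dx − du/dy at interior grid corners
    dvdx = (v[1:, 1:-1] - v[:-1, 1:-1]) / h
    dudy = (u[1:-1, 1:] - u[1:-1, :-1]) / h
    omega = dvdx - dudy
    xs = domain.origin[0] + np.arange(1, omega.shape[0] + 1) * h  # corner x
    left = float(omega[xs < 0, :].sum() * h * h)
    right = float(omega[xs > 0, :].sum() * h * h)
    floor = noise_floor_frac * max(abs(left), abs(right))
    recirc = (left * right < 0) and min(abs(left), abs(right)) > floor
    return left, right, recirc


@dataclass
class RampScanResult:
    """Rows of (ramp multiplier, time to max depth, max depth)."""

    table: pd.DataFrame

    def depths(self) -> np.ndarray:
        return self.table["max_depth_um"].to_numpy()


def ramp_scan(
    geometry: EmbryoGeometry,
    protocol_template: ForceProtocol,
    params_template: SimulationParams,
    domain: FluidDomain,
    multipliers,
) -> RampScanResult:
    """Run the simulation for each ramp-duration multiplier (ramp time and
    ``t_max`` both scaled) and collect (time-to-max, max depth) per row.

    Failures in individual runs are recorded as NaN rows and the scan
    continues.
    """
    multipliers = list(multipliers)
    if not multipliers or any(m < 1 for m in multipliers):
        raise ValueError("multipliers must be a non-empty list of values >= 1")
    rows = []
    for m in multipliers:
        proto = protocol_template.rescaled(m)
        params = SimulationParams(
            dt=params_template.dt,
            t_max=params_template.t_max * m,
            sample_every=params_template.sample_every,
            stop_window_frac=params_template.stop_window_frac,
            stop_depth_frac=params_template.stop_depth_frac,
            min_time=params_template.min_time * m,
            density=params_template.density,
        )
        try:
            traj = run_simulation(geometry, proto, params, domain)
            t_peak, plateaued = time_to_max_depth(traj)
            rows.append(
                {
                    "multiplier": m,
                    "time_to_max_s": t_peak,
                    "max_depth_um": float(traj.depth.max()),
                    "plateaued": plateaued,
                }
            )
        except (FloatingPointError, RuntimeError, ValueError) as exc:  # keep scanning
            rows.append(
                {
                    "multiplier": m,
                    "time_to_max_s": np.nan,
                    "max_depth_um": np.nan,
                    "plateaued": False,
                    "error": str(exc),
                }
            )
    return RampScanResult(table=pd.DataFrame(rows))
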