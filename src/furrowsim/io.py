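"""Serialization: trajectory HDF5 files and VTK legacy exports.

The trajectory layout::

    /times              (n_samples,)          s
    /positions          (n_samples, N, dim)   µm
    /depth              (n_samples,)          µm
    /volumes/<name>     per-compartment measure series
    /flow/u, /flow/v[, /flow/w]   final staggered velocity field
    attrs: geometry (JSON), protocol (JSON), params (JSON), stopped_on_plateau

VTK exports use the legacy ASCII format (a plain-text format simple enough
to emit directly): spring networks as polydata lines, triangle meshes as
polydata triangles, velocity snapshots as structured points with cell-centre
vectors.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .geometry import EmbryoGeometry
from .ibm import SimulationParams, Trajectory
from .mechanics import ForceProtocol
from .stokes import FluidDomain, VelocityField

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "write_vtk_mesh",
    "write_vtk_velocity",
]


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions, compression="gzip")
        f.create_dataset("depth", data=traj.depth)
        vg = f.create_group("volumes")
        for k, v in traj.volumes.items():
            vg.create_dataset(k, data=v)
        if traj.flow is not None:
            fg = f.create_group("flow")
            for a, comp in enumerate(traj.flow.components):
                fg.create_dataset("uvw"[a], data=comp)
        f.attrs["geometry"] = traj.geometry.to_json()
        f.attrs["protocol"] = json.dumps(traj.protocol.to_dict())
        f.attrs["params"] = json.dumps(
            {
                "dt": traj.params.dt,
                "t_max": traj.params.t_max,
                "sample_every": traj.params.sample_every,
                "min_time": traj.params.min_time,
            }
        )
        f.attrs["stopped_on_plateau"] = traj.stopped_on_plateau


def load_trajectory(path, domain: FluidDomain | None = None) -> Trajectory:
    """Read a trajectory file back.  The fluid domain is not serialized;
    pass one if downstream analysis needs it."""
    with h5py.File(path, "r") as f:
        geometry = EmbryoGeometry.from_json(f.attrs["geometry"])
        proto = ForceProtocol.from_dict(json.loads(f.attrs["protocol"]))
        p = json.loads(f.attrs["params"])
        params = SimulationParams(
            dt=p["dt"], t_max=p["t_max"], sample_every=p["sample_every"],
            min_time=p.get("min_time", 0.0),
        )
        flow = None
        if "flow" in f:
            comps = tuple(f["flow"]["uvw"[a]][...] for a in range(geometry.dim))
            flow = VelocityField(components=comps)
        return Trajectory(
            times=f["times"][...],
            positions=f["positions"][...],
            volumes={k: v[...] for k, v in f["volumes"].items()},
            depth=f["depth"][...],
            geometry=geometry,
            domain=domain,
            protocol=proto,
            params=params,
            flow=flow,
            stopped_on_plateau=bool(f.attrs["stopped_on_plateau"]),
        )


def write_vtk_mesh(geometry: EmbryoGeometry, path, positions: np.ndarray | None = None) -> None:
    """Write the spring network (2D: lines; 3D: triangles + lines) as legacy
    ASCII VTK polydata with the membrane class as cell data."""
    pos = geometry.nodes if positions is None else positions
    pts = np.column_stack([pos, np.zeros(len(pos))]) if geometry.dim == 2 else pos
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nspring network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            f.write("%.6f %.6f %.6f\n" % tuple(p))
        if geometry.faces is not None:
            tri = geometry.faces
            f.write(f"POLYGONS {len(tri)} {4 * len(tri)}\n")
            for t in tri:
                f.write("3 %d %d %d\n" % tuple(t))
            f.write(f"CELL_DATA {len(tri)}\nSCALARS membrane_class int 1\n")
            f.write("LOOKUP_TABLE default\n")
            for c in geometry.face_class:
                f.write(f"{int(c)}\n")
        else:
            e = geometry.edges
            f.write(f"LINES {len(e)} {3 * len(e)}\n")
            for a, b in e:
                f.write(f"2 {a} {b}\n")
            f.write(f"CELL_DATA {len(e)}\nSCALARS membrane_class int 1\n")
            f.write("LOOKUP_TABLE default\n")
            for c in geometry.edge_class:
                f.write(f"{int(c)}\n")


def write_vtk_velocity(domain: FluidDomain, vel: VelocityField, path) -> None:
    """Write a velocity snapshot as legacy ASCII structured points, with the
    staggered components averaged to cell centres."""
    dim = domain.dim
    centered = []
    for a in range(dim):
        c = vel.components[a]
        hi = tuple(slice(1, None) if b == a else slice(None) for b in range(dim))
        lo = tuple(slice(0, -1) if b == a else slice(None) for b in range(dim))
        centered.append(0.5 * (c[hi] + c[lo]))
    if dim == 2:
        centered.append(np.zeros_like(centered[0]))
        nx, ny, nz = domain.shape[0], domain.shape[1], 1
        origin = (*domain.origin, 0.0)
    else:
        nx, ny, nz = domain.shape
        origin = tuple(domain.origin)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvelocity\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write("ORIGIN %.6f %.6f %.6f\n" % origin)
        f.write("SPACING %.6f %.6f %.6f\n" % (domain.h, domain.h, domain.h))
        f.write(f"POINT_DATA {nx * ny * nz}\nVECTORS velocity float\n")
        flat = [c.reshape(nx, ny, nz if dim == 3 else 1, order="C") for c in centered]
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    f.write(
                        "%.6e %.6e %.6e\n"
                        % (flat[0][i, j, k], flat[1][i, j, k], flat[2][i, j, k])
                    )
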