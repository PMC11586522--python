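"""Embryo geometry construction for the ventral-furrow model.

The embryonic cross-section is represented as a ring of quadrilateral cells
sandwiched between the yolk (inside) and the perivitelline space (outside),
enclosed by a rigid circular vitelline boundary.  Every membrane — apical
(outward-facing), lateral (radial, shared between neighbours) and basal
(yolk-facing) — is discretized as a chain of short Hookean springs.

Conventions
-----------
* The ventral midline points straight down (angle −π/2).  Lateral membrane
  boundaries carry signed integer positions ``s``; the membrane at ``s = 0``
  lies exactly on the midline, negative positions are to its left.  The cell
  with signed index ``s`` spans boundaries ``s`` and ``s + 1``.
* Mesodermal cells are the contiguous block of cells centred on the midline.
* Lengths are in µm.  Spring stiffnesses follow ``k = K_m / ℓ0`` where
  ``K_m`` is the membrane stretch modulus (E·h per unit depth in 2D).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "APICAL",
    "LATERAL",
    "BASAL",
    "CLASS_NAMES",
    "Cell",
    "EmbryoGeometry",
    "build_cross_section_2d",
    "remove_basal_membranes",
    "polygon_area",
]

APICAL, LATERAL, BASAL = 0, 1, 2
CLASS_NAMES = {APICAL: "apical", LATERAL: "lateral", BASAL: "basal"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as an (n, 2) array.

    The closing segment from the last to the first vertex is implicit.
    Counter-clockwise orientation gives a positive area.
    """
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Cell:
    """One epithelial cell: ordered node chains of its four membranes.

    Chains are node-index sequences.  ``apical`` and ``basal`` run from the
    cell's left boundary to its right boundary; ``lateral_left`` and
    ``lateral_right`` run from the basal ring to the apical ring.  After
    basal-membrane removal ``basal`` is ``None`` and the cell is open to the
    yolk.
    """

    index: int
    apical: np.ndarray
    basal: np.ndarray | None
    lateral_left: np.ndarray
    lateral_right: np.ndarray
    edges: np.ndarray

    @property
    def open(self) -> bool:
        return self.basal is None

    def polygon(self) -> np.ndarray:
        """Ordered node loop bounding the cell.

        For an open cell the loop is closed by the straight chord between
        the basal endpoints of the two lateral membranes, which defines the
        cell's *retained* region for volume bookkeeping.
        """
        if self.basal is not None:
            bottom = self.basal
        else:
            bottom = np.array([self.lateral_left[0], self.lateral_right[0]])
        loop = np.concatenate(
            [
                bottom[:-1],
                self.lateral_right[:-1],
                self.apical[::-1][:-1],
                self.lateral_left[::-1][:-1],
            ]
        )
        # the chain order above walks the quad clockwise; flip to CCW so the
        # shoelace area comes out positive
        return loop[::-1]


@dataclass
class EmbryoGeometry:
    """Spring-network embryo geometry (2D ring or 3D spheroid shell).

    ``nodes`` is (N, dim); ``edges`` is (E, 2) int; ``edge_class`` holds
    APICAL/LATERAL/BASAL codes; ``edge_mesoderm`` marks edges belonging to a
    mesodermal cell.  ``laterals`` maps signed boundary position → edge ids
    of that lateral chain (used for membrane-length profiles).
    """

    dim: int
    nodes: np.ndarray
    edges: np.ndarray
    edge_class: np.ndarray
    rest_length: np.ndarray
    stiffness: np.ndarray
    cells: list[Cell]
    mesoderm_ids: np.ndarray
    edge_mesoderm: np.ndarray
    vitelline_radius: float
    perivitelline_gap: float
    cell_height: float
    basal_open: bool = False
    laterals: dict[int, np.ndarray] = field(default_factory=dict)
    midline_apical_nodes: np.ndarray = field(default_factory=lambda: np.array([], int))
    # 3D-only fields
    faces: np.ndarray | None = None
    face_class: np.ndarray | None = None
    semi_axes: tuple[float, float, float] | None = None
    cells3d: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell(self, signed_index: int) -> Cell:
        for c in self.cells:
            if c.index == signed_index:
                return c
        raise KeyError(f"no cell with signed index {signed_index}")

    def edge_ids_of_class(self, cls: int) -> np.ndarray:
        return np.nonzero(self.edge_class == cls)[0]

    def edge_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.nodes if positions is None else positions
        d = pos[self.edges[:, 1]] - pos[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def outer_boundary_loop(self) -> np.ndarray:
        """Node loop of the embryo's outer (apical) surface, 2D only."""
        chunks = [c.apical[:-1] for c in self.cells]
        return np.concatenate(chunks)

    def yolk_polygon(self) -> np.ndarray:
        """Node loop bounding the yolk compartment (2D, closed cells only)."""
        if self.basal_open:
            raise ValueError("yolk polygon undefined once basal membranes are open")
        chunks = [c.basal[:-1] for c in self.cells]
        return np.concatenate(chunks)

    # ---------------------------------------------------------------- io
    def to_json(self) -> str:
        payload = {
            "dim": self.dim,
            "nodes": self.nodes.tolist(),
            "edges": self.edges.tolist(),
            "edge_class": [CLASS_NAMES[c] for c in self.edge_class],
            "rest_length": self.rest_length.tolist(),
            "stiffness": self.stiffness.tolist(),
            "edge_mesoderm": self.edge_mesoderm.astype(int).tolist(),
            "mesoderm_ids": self.mesoderm_ids.tolist(),
            "vitelline_radius": self.vitelline_radius,
            "perivitelline_gap": self.perivitelline_gap,
            "cell_height": self.cell_height,
            "basal_open": self.basal_open,
            "midline_apical_nodes": self.midline_apical_nodes.tolist(),
            "laterals": {str(k): v.tolist() for k, v in self.laterals.items()},
            "cells": [
                {
                    "index": c.index,
                    "apical": c.apical.tolist(),
                    "basal": None if c.basal is None else c.basal.tolist(),
                    "lateral_left": c.lateral_left.tolist(),
                    "lateral_right": c.lateral_right.tolist(),
                    "edges": c.edges.tolist(),
                }
                for c in self.cells
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EmbryoGeometry":
        d = json.loads(text)
        cells = [
            Cell(
                index=c["index"],
                apical=np.asarray(c["apical"], int),
                basal=None if c["basal"] is None else np.asarray(c["basal"], int),
                lateral_left=np.asarray(c["lateral_left"], int),
                lateral_right=np.asarray(c["lateral_right"], int),
                edges=np.asarray(c["edges"], int),
            )
            for c in d["cells"]
        ]
        return cls(
            dim=d["dim"],
            nodes=np.asarray(d["nodes"], float),
            edges=np.asarray(d["edges"], int),
            edge_class=np.asarray([CLASS_CODES[n] for n in d["edge_class"]], np.int8),
            rest_length=np.asarray(d["rest_length"], float),
            stiffness=np.asarray(d["stiffness"], float),
            cells=cells,
            mesoderm_ids=np.asarray(d["mesoderm_ids"], int),
            edge_mesoderm=np.asarray(d["edge_mesoderm"], bool),
            vitelline_radius=d["vitelline_radius"],
            perivitelline_gap=d["perivitelline_gap"],
            cell_height=d["cell_height"],
            basal_open=d["basal_open"],
            midline_apical_nodes=np.asarray(d["midline_apical_nodes"], int),
            laterals={int(k): np.asarray(v, int) for k, v in d["laterals"].items()},
        )


# ---------------------------------------------------------------------------
# 2D builder
# ---------------------------------------------------------------------------


def _chain_counts(length: float, nodes_per_membrane: int, spacing: float | None) -> int:
    if spacing is not None:
        return max(1, int(np.ceil(length / spacing)))
    return nodes_per_membrane


def build_cross_section_2d(
    n_cells: int = 80,
    radius: float = 90.0,
    cell_height: float = 35.0,
    gap: float = 5.0,
    nodes_per_membrane: int = 4,
    n_mesoderm: int = 16,
    spacing: float | None = None,
    stretch_modulus: float = 1.0,
) -> EmbryoGeometry:
    """Build the transverse 2D cross-section of the embryonic epithelium.

    A ring of ``n_cells`` radially oriented quadrilateral cells sits between
    the circular vitelline boundary (``radius``) and the central yolk.  The
    apical surface lies at ``radius − gap``; the basal surface at
    ``radius − gap − cell_height``.  The ``n_mesoderm`` contiguous cells
    centred on the ventral midline (bottom of the circle) are flagged
    contractile.

    Each membrane is subdivided into ``nodes_per_membrane`` springs, unless
    ``spacing`` is given, in which case each membrane gets
    ``ceil(length / spacing)`` springs of roughly equal length.  Rest lengths
    equal the as-built segment lengths; stiffness is
    ``stretch_modulus / rest_length``.
    """
    if radius <= 0 or cell_height <= 0 or gap <= 0 or n_cells <= 0:
        raise ValueError("geometry dimensions must be positive")
    if nodes_per_membrane < 1:
        raise ValueError("nodes_per_membrane must be >= 1")
    if n_mesoderm < 1 or n_mesoderm > n_cells:
        raise ValueError("require 1 <= n_mesoderm <= n_cells")
    if radius <= cell_height + gap:
        raise ValueError("radius must exceed cell_height + gap")

    r_a = radius - gap
    r_b = r_a - cell_height
    n = n_cells
    dtheta = 2.0 * np.pi / n

    def theta(s: int) -> float:
        return -np.pi / 2.0 + s * dtheta

    signed = list(range(-(n // 2), n - n // 2))  # boundary & cell signed indices

    nodes: list[tuple[float, float]] = []

    def add_node(x: float, y: float) -> int:
        nodes.append((x, y))
        return len(nodes) - 1

    corner_b = {s: add_node(r_b * np.cos(theta(s)), r_b * np.sin(theta(s))) for s in signed}
    corner_a = {s: add_node(r_a * np.cos(theta(s)), r_a * np.sin(theta(s))) for s in signed}

    def next_s(s: int) -> int:
        return signed[(signed.index(s) + 1) % n]

    # lateral chains: straight radial subdivision from basal to apical corner
    lat_chain: dict[int, np.ndarray] = {}
    n_lat = _chain_counts(cell_height, nodes_per_membrane, spacing)
    for s in signed:
        th = theta(s)
        ids = [corner_b[s]]
        for j in range(1, n_lat):
            r = r_b + (r_a - r_b) * j / n_lat
            ids.append(add_node(r * np.cos(th), r * np.sin(th)))
        ids.append(corner_a[s])
        lat_chain[s] = np.asarray(ids, int)

    # apical / basal arcs per cell
    def arc_chain(s: int, r: float, corners: dict[int, int], count: int) -> np.ndarray:
        s2 = next_s(s)
        th0, th1 = theta(s), theta(s) + dtheta
        ids = [corners[s]]
        for j in range(1, count):
            th = th0 + (th1 - th0) * j / count
            ids.append(add_node(r * np.cos(th), r * np.sin(th)))
        ids.append(corners[s2])
        return np.asarray(ids, int)

    n_api = _chain_counts(r_a * dtheta, nodes_per_membrane, spacing)
    n_bas = _chain_counts(r_b * dtheta, nodes_per_membrane, spacing)
    api_chain = {s: arc_chain(s, r_a, corner_a, n_api) for s in signed}
    bas_chain = {s: arc_chain(s, r_b, corner_b, n_bas) for s in signed}

    # mesoderm block centred on midline: cells -m//2 .. m - m//2 - 1
    m = n_mesoderm
    meso = set(range(-(m // 2), m - m // 2))

    edges: list[tuple[int, int]] = []
    edge_class: list[int] = []
    edge_meso: list[bool] = []
    edge_owner: dict[tuple[str, int], list[int]] = {}

    def add_chain_edges(chain: np.ndarray, cls: int, is_meso: bool, key: tuple[str, int]):
        ids = []
        for a, b in zip(chain[:-1], chain[1:]):
            edges.append((int(a), int(b)))
            edge_class.append(cls)
            edge_meso.append(is_meso)
            ids.append(len(edges) - 1)
        edge_owner[key] = ids

    for s in signed:
        prev_cell = signed[(signed.index(s) - 1) % n]
        lat_meso = (s in meso) or (prev_cell in meso)
        add_chain_edges(lat_chain[s], LATERAL, lat_meso, ("lat", s))
    for s in signed:
        add_chain_edges(api_chain[s], APICAL, s in meso, ("api", s))
    for s in signed:
        add_chain_edges(bas_chain[s], BASAL, s in meso, ("bas", s))

    cells = []
    for s in signed:
        s2 = next_s(s)
        cell_edges = np.asarray(
            edge_owner[("api", s)]
            + edge_owner[("bas", s)]
            + edge_owner[("lat", s)]
            + edge_owner[("lat", s2)],
            int,
        )
        cells.append(
            Cell(
                index=s,
                apical=api_chain[s],
                basal=bas_chain[s],
                lateral_left=lat_chain[s],
                lateral_right=lat_chain[s2],
                edges=cell_edges,
            )
        )

    node_arr = np.asarray(nodes, float)
    edge_arr = np.asarray(edges, int)
    d = node_arr[edge_arr[:, 1]] - node_arr[edge_arr[:, 0]]
    rest = np.linalg.norm(d, axis=1)
    stiff = stretch_modulus / rest

    laterals = {s: np.asarray(edge_owner[("lat", s)], int) for s in signed}

    return EmbryoGeometry(
        dim=2,
        nodes=node_arr,
        edges=edge_arr,
        edge_class=np.asarray(edge_class, np.int8),
        rest_length=rest,
        stiffness=stiff,
        cells=cells,
        mesoderm_ids=np.asarray(sorted(meso), int),
        edge_mesoderm=np.asarray(edge_meso, bool),
        vitelline_radius=radius,
        perivitelline_gap=gap,
        cell_height=cell_height,
        basal_open=False,
        laterals=laterals,
        midline_apical_nodes=np.asarray([corner_a[0]], int),
    )


# ---------------------------------------------------------------------------
# basal-membrane removal
# ---------------------------------------------------------------------------


def remove_basal_membranes(geometry: EmbryoGeometry) -> EmbryoGeometry:
    """Return a copy of ``geometry`` with every basal-class element removed.

    Cell interiors become continuous with the yolk compartment; lateral and
    apical membranes (and their shared corner nodes) are untouched.  Interior
    basal nodes that no longer carry any spring are dropped and all indices
    are remapped.  Calling this on an already-open geometry is a warned no-op.
    """
    if geometry.basal_open:
        warnings.warn("geometry already has open basal surfaces; no-op", stacklevel=2)
        return replace(geometry)

    keep_edge = geometry.edge_class != BASAL
    if geometry.faces is not None:
        keep_face = geometry.face_class != BASAL
        face_map = -np.ones(len(geometry.faces), int)
        face_map[keep_face] = np.arange(int(keep_face.sum()))
    edge_map = -np.ones(len(geometry.edges), int)
    edge_map[keep_edge] = np.arange(int(keep_edge.sum()))

    new_edges = geometry.edges[keep_edge]
    used = np.zeros(len(geometry.nodes), bool)
    used[new_edges.ravel()] = True
    if geometry.faces is not None:
        used[geometry.faces[keep_face].ravel()] = True
    node_map = -np.ones(len(geometry.nodes), int)
    node_map[used] = np.arange(int(used.sum()))

    def remap_chain(chain: np.ndarray | None) -> np.ndarray | None:
        if chain is None:
            return None
        return node_map[chain]

    cells = [
        Cell(
            index=c.index,
            apical=remap_chain(c.apical),
            basal=None,
            lateral_left=remap_chain(c.lateral_left),
            lateral_right=remap_chain(c.lateral_right),
            edges=edge_map[c.edges][edge_map[c.edges] >= 0],
        )
        for c in geometry.cells
    ]

    return EmbryoGeometry(
        dim=geometry.dim,
        nodes=geometry.nodes[used],
        edges=node_map[new_edges],
        edge_class=geometry.edge_class[keep_edge],
        rest_length=geometry.rest_length[keep_edge],
        stiffness=geometry.stiffness[keep_edge],
        cells=cells,
        mesoderm_ids=geometry.mesoderm_ids.copy(),
        edge_mesoderm=geometry.edge_mesoderm[keep_edge],
        vitelline_radius=geometry.vitelline_radius,
        perivitelline_gap=geometry.perivitelline_gap,
        cell_height=geometry.cell_height,
        basal_open=True,
        laterals={k: edge_map[v] for k, v in geometry.laterals.items()},
        midline_apical_nodes=node_map[geometry.midline_apical_nodes],
        faces=None if geometry.faces is None else node_map[geometry.faces[keep_face]],
        face_class=None if geometry.face_class is None else geometry.face_class[keep_face],
        semi_axes=geometry.semi_axes,
        cells3d=[
            replace(
                c,
                apical_faces=face_map[c.apical_faces],
                basal_faces=None,
                lateral_faces=face_map[c.lateral_faces],
            )
            for c in geometry.cells3d
        ],
    )


# ---------------------------------------------------------------------------
# 3D spheroid builder
# ---------------------------------------------------------------------------


@dataclass
class Cell3D:
    """Prism-like 3D cell: indices of the triangles forming its closed
    bounding surface, grouped by membrane class."""

    index: tuple[int, int]  # (band along the long axis, azimuthal sector)
    apical_faces: np.ndarray
    basal_faces: np.ndarray | None
    lateral_faces: np.ndarray
    is_mesoderm: bool = False

    def face_ids(self) -> np.ndarray:
        parts = [self.apical_faces, self.lateral_faces]
        if self.basal_faces is not None:
            parts.append(self.basal_faces)
        return np.concatenate(parts)


def cell_volume_3d(nodes: np.ndarray, faces: np.ndarray) -> float:
    """Volume of a closed triangulated surface by the divergence theorem.

    Winding is not assumed consistent with outward normals; the absolute
    signed sum is returned.
    """
    v0 = nodes[faces[:, 0]]
    v1 = nodes[faces[:, 1]]
    v2 = nodes[faces[:, 2]]
    return abs(float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)


def build_embryo_3d(
    semi_axes: tuple[float, float, float] = (230.0, 90.0, 90.0),
    n_bands: int = 8,
    n_azimuth: int = 16,
    cell_height: float = 35.0,
    gap: float = 8.0,
    band_extent: float = 0.7,
    resolution: int = 1,
    n_mesoderm_bands: int = 4,
    mesoderm_half_angle: float = 0.45,
    stretch_modulus: float = 1.0,
) -> EmbryoGeometry:
    """Tessellate a prolate-spheroid epithelium into prism-like cells.

    The long (antero-posterior) axis is x; the epithelium is the band
    |x| ≤ ``band_extent``·a, divided into ``n_bands`` × ``n_azimuth`` cells
    bounded by the outer (apical) surface — the spheroid offset inward by
    ``gap`` — and an inner (basal) surface a further ``cell_height`` inward.
    ``resolution`` subdivides every quad patch, controlling triangle count;
    the mesoderm is the ventral patch of ``n_mesoderm_bands`` central bands
    within ``mesoderm_half_angle`` radians of the ventral midline.

    Every cell's bounding surface is watertight (each interior edge shared
    by exactly two of its triangles); zero-area triangles are rejected.
    """
    if resolution < 1 or n_bands < 1 or n_azimuth < 3:
        raise ValueError("invalid tessellation parameters")
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= gap + cell_height:
        raise ValueError("semi-axes must exceed gap + cell_height")

    res = resolution
    nu = n_bands * res          # sub-quads along x
    nv = n_azimuth * res        # sub-quads around the azimuth (periodic)
    us = np.linspace(-band_extent, band_extent, nu + 1)  # normalised x
    phis = np.linspace(-np.pi, np.pi, nv + 1)[:-1] - np.pi / 2.0

    outer_axes = np.array([a - gap, b - gap, c - gap])
    inner_axes = outer_axes - cell_height

    nodes: list[np.ndarray] = []

    def add(p) -> int:
        nodes.append(np.asarray(p, float))
        return len(nodes) - 1

    def surf_point(axes, u, phi):
        x = u * axes[0]
        r = np.sqrt(max(1.0 - u * u, 0.0))
        return np.array([x, axes[1] * r * np.cos(phi), axes[2] * r * np.sin(phi)])

    outer = np.array([[add(surf_point(outer_axes, u, p)) for p in phis] for u in us])
    inner = np.array([[add(surf_point(inner_axes, u, p)) for p in phis] for u in us])

    # radial wall vertices between inner and outer, on every band boundary
    # (fixed u-line) and sector boundary (fixed phi-line); r = 0 is inner
    n_r = res
    wall: dict[tuple[int, int, int], int] = {}
    for iu in range(nu + 1):
        for iv in range(nv):
            if iu % res != 0 and iv % res != 0:
                continue
            for ir in range(1, n_r):
                f = ir / n_r
                p = (1 - f) * nodes[inner[iu, iv]] + f * nodes[outer[iu, iv]]
                wall[(iu, iv, ir)] = add(p)

    def radial(iu, iv, ir):
        if ir == 0:
            return inner[iu, iv % nv]
        if ir == n_r:
            return outer[iu, iv % nv]
        return wall[(iu, iv % nv, ir)]

    faces: list[tuple[int, int, int]] = []
    face_class: list[int] = []

    def quad(p00, p10, p11, p01, cls) -> list[int]:
        ids = []
        for tri in ((p00, p10, p11), (p00, p11, p01)):
            faces.append(tri)
            face_class.append(cls)
            ids.append(len(faces) - 1)
        return ids

    def patch(grid_fn, i0, j0, cls) -> np.ndarray:
        ids = []
        for di in range(res):
            for dj in range(res):
                ids += quad(
                    grid_fn(i0 + di, j0 + dj),
                    grid_fn(i0 + di + 1, j0 + dj),
                    grid_fn(i0 + di + 1, j0 + dj + 1),
                    grid_fn(i0 + di, j0 + dj + 1),
                    cls,
                )
        return np.asarray(ids, int)

    meso_band_lo = (n_bands - n_mesoderm_bands) // 2
    meso_band_hi = meso_band_lo + n_mesoderm_bands

    cells3d: list[Cell3D] = []
    for bi in range(n_bands):
        for sj in range(n_azimuth):
            iu, iv = bi * res, sj * res
            api = patch(lambda i, j: outer[i, j % nv], iu, iv, APICAL)
            bas = patch(lambda i, j: inner[i, j % nv], iu, iv, BASAL)
            lats = []
            for side_iu in (iu, iu + res):  # walls normal to x
                lats.append(patch(lambda j, r, _iu=side_iu: radial(_iu, j, r), iv, 0, LATERAL))
            for side_iv in (iv, iv + res):  # walls normal to phi
                lats.append(patch(lambda i, r, _iv=side_iv: radial(i, _iv, r), iu, 0, LATERAL))
            cells3d.append(
                Cell3D(
                    index=(bi, sj),
                    apical_faces=api,
                    basal_faces=bas,
                    lateral_faces=np.concatenate(lats),
                )
            )

    node_arr = np.vstack(nodes)
    face_arr = np.asarray(faces, int)
    fclass = np.asarray(face_class, np.int8)

    # mesoderm flag by geometric test on cell centroids (ventral = -z)
    for cell in cells3d:
        tri = face_arr[cell.face_ids()]
        centroid = node_arr[np.unique(tri)].mean(axis=0)
        phi = np.arctan2(centroid[2], centroid[1])
        band_ok = meso_band_lo <= cell.index[0] < meso_band_hi
        cell.is_mesoderm = band_ok and abs(phi + np.pi / 2) < mesoderm_half_angle

    # reject degenerate triangles
    v0, v1, v2 = (node_arr[face_arr[:, k]] for k in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    if np.any(areas <= 1e-9):
        raise ValueError("tessellation produced zero-area triangles")

    # spring network: unique triangle edges, class = least-open membrane
    # class among adjacent faces (APICAL < LATERAL < BASAL), so edges shared
    # between a basal and a lateral patch survive basal removal
    e_all = np.vstack([face_arr[:, [0, 1]], face_arr[:, [1, 2]], face_arr[:, [2, 0]]])
    e_cls = np.concatenate([fclass, fclass, fclass])
    e_sorted = np.sort(e_all, axis=1)
    uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
    edge_class = np.full(len(uniq), 127, np.int8)
    np.minimum.at(edge_class, inv, e_cls)

    meso_faces = np.zeros(len(face_arr), bool)
    for cell in cells3d:
        if cell.is_mesoderm:
            meso_faces[cell.face_ids()] = True
    edge_meso = np.zeros(len(uniq), bool)
    np.logical_or.at(edge_meso, inv, np.repeat(meso_faces, 3))

    rest = np.linalg.norm(node_arr[uniq[:, 1]] - node_arr[uniq[:, 0]], axis=1)
    stiff = np.full(len(uniq), np.sqrt(3.0) / 2.0 * stretch_modulus)

    midline = outer[nu // 2, int(np.argmin(np.abs(phis + np.pi / 2)))]

    return EmbryoGeometry(
        dim=3,
        nodes=node_arr,
        edges=uniq,
        edge_class=edge_class,
        rest_length=rest,
        stiffness=stiff,
        cells=[],
        mesoderm_ids=np.asarray(
            [i for i, cl in enumerate(cells3d) if cl.is_mesoderm], int
        ),
        edge_mesoderm=edge_meso,
        vitelline_radius=float(min(b, c)),
        perivitelline_gap=gap,
        cell_height=cell_height,
        basal_open=False,
        laterals={},
        midline_apical_nodes=np.asarray([midline], int),
        faces=face_arr,
        face_class=fclass,
        semi_axes=(a, b, c),
        cells3d=cells3d,
    )
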