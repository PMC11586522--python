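"""Incompressible Stokes flow with spatially varying viscosity.

The fluid occupies the interior of the rigid vitelline boundary and is in
the zero-Reynolds-number regime: velocity is determined instantaneously by
the force density,

    −∇·(η(∇u + ∇uᵀ)) + ∇p = f,     ∇·u = 0,     u = 0 on the boundary.

Discretization is a MAC staggered finite-difference grid (pressure at cell
centres, velocity components at faces) in 2D or 3D.  The boundary is imposed
by direct masking: a pressure cell is active when its centre lies inside the
fluid region, a velocity face is active when both flanking pressure cells
are, and every inactive degree of freedom is pinned to zero.  With this rule
the discrete divergence telescopes exactly over the active region, so
dropping one (redundant) continuity row to fix the pressure gauge is
mass-exact.

The saddle-point system is factorized once per domain (SuperLU) and reused
for every subsequent solve: domain, mask and viscosity field are static over
a simulation, so each immersed-boundary time step costs only triangular
solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = ["FluidDomain", "VelocityField", "solve_stokes", "discrete_divergence"]


@dataclass
class VelocityField:
    """Staggered velocity: ``components[a]`` lives on the a-faces of the grid."""

    components: tuple[np.ndarray, ...]
    pressure: np.ndarray | None = None

    @property
    def u(self) -> np.ndarray:
        return self.components[0]

    @property
    def v(self) -> np.ndarray:
        return self.components[1]

    def max_abs(self) -> float:
        return max(float(np.abs(c).max()) for c in self.components)

    def scaled(self, factor: float) -> "VelocityField":
        return VelocityField(
            components=tuple(factor * c for c in self.components),
            pressure=None if self.pressure is None else factor * self.pressure,
        )


def _lookup(arr: np.ndarray, coords: list[np.ndarray]) -> np.ndarray:
    """Index ``arr`` at integer coordinate grids, −1 where out of range."""
    ok = np.ones(coords[0].shape, bool)
    clipped = []
    for c, n in zip(coords, arr.shape):
        ok &= (c >= 0) & (c < n)
        clipped.append(np.clip(c, 0, n - 1))
    return np.where(ok, arr[tuple(clipped)], -1)


class FluidDomain:
    """Regular MAC grid covering a box with a masked fluid region inside.

    Parameters
    ----------
    origin : lower corner of the bounding box (length ``dim``).
    shape : number of pressure cells per axis.
    h : uniform grid spacing (µm).
    inside : callable mapping an (M, dim) point array to a boolean fluid mask;
        ``None`` means the whole box is fluid (no-slip walls on its boundary).
    viscosity : callable mapping points to viscosity (Pa·s), or a scalar.
    """

    def __init__(self, origin, shape, h, inside=None, viscosity=1.0):
        self.origin = np.asarray(origin, float)
        self.shape = tuple(int(s) for s in shape)
        self.dim = len(self.shape)
        self.h = float(h)
        if self.dim not in (2, 3):
            raise ValueError("only 2D and 3D grids are supported")

        centers = self.cell_centers()
        flat = centers.reshape(-1, self.dim)
        if inside is None:
            self.p_active = np.ones(self.shape, bool)
        else:
            self.p_active = np.asarray(inside(flat), bool).reshape(self.shape)
        if callable(viscosity):
            self.eta_center = np.asarray(viscosity(flat), float).reshape(self.shape)
        else:
            self.eta_center = np.full(self.shape, float(viscosity))
        if np.any(self.eta_center <= 0):
            raise ValueError("viscosity must be positive everywhere")

        # a velocity face is active iff both flanking pressure cells are active
        self.face_active = []
        for a in range(self.dim):
            pad = [(1, 1) if b == a else (0, 0) for b in range(self.dim)]
            padded = np.pad(self.p_active, pad, constant_values=False)
            lo = tuple(slice(0, -1) if b == a else slice(None) for b in range(self.dim))
            hi = tuple(slice(1, None) if b == a else slice(None) for b in range(self.dim))
            self.face_active.append(padded[lo] & padded[hi])

        self._n_face = [int(np.prod(self.face_shape(a))) for a in range(self.dim)]
        self._offset = np.concatenate([[0], np.cumsum(self._n_face)])
        self.n_dof = int(self._offset[-1] + np.prod(self.shape))
        self._A: sp.csc_matrix | None = None
        self._lu = None

    # ------------------------------------------------------------ geometry
    def cell_centers(self) -> np.ndarray:
        axes = [self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.h
                for a in range(self.dim)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def face_shape(self, a: int) -> tuple[int, ...]:
        return tuple(s + 1 if b == a else s for b, s in enumerate(self.shape))

    def face_origin(self, a: int) -> np.ndarray:
        """Position of face (0, ..., 0) for component ``a``: staggered by h/2
        along every axis except ``a``."""
        off = np.full(self.dim, 0.5 * self.h)
        off[a] = 0.0
        return self.origin + off

    def zero_force(self) -> tuple[np.ndarray, ...]:
        return tuple(np.zeros(self.face_shape(a)) for a in range(self.dim))

    @property
    def cell_measure(self) -> float:
        return self.h**self.dim

    # ------------------------------------------------------------ factories
    @classmethod
    def disk(cls, radius, gap, eta, eta_pv, n, margin=2.0):
        """Vitelline-disk domain: interior viscosity ``eta`` with a
        low-viscosity perivitelline annulus of width ``gap`` just inside the
        no-slip circle of the given ``radius``."""
        L = radius + margin
        h = 2 * L / n

        def inside(pts):
            return np.linalg.norm(pts, axis=1) < radius

        def viscosity(pts):
            r = np.linalg.norm(pts, axis=1)
            return np.where(r < radius - gap, eta, eta_pv)

        return cls(origin=(-L, -L), shape=(n, n), h=h, inside=inside, viscosity=viscosity)

    @classmethod
    def box(cls, lengths, n, eta=1.0):
        """Closed rectangular cavity with no-slip walls on the box boundary."""
        lengths = np.atleast_1d(np.asarray(lengths, float))
        n = np.atleast_1d(np.asarray(n, int))
        h = lengths[0] / n[0]
        if not np.allclose(lengths / n, h):
            raise ValueError("grid spacing must be uniform across axes")
        return cls(origin=np.zeros(len(lengths)), shape=tuple(n), h=h, viscosity=eta)

    @classmethod
    def spheroid(cls, semi_axes, gap, eta, eta_pv, n, margin=2.0):
        """Prolate-spheroid vitelline domain (3D); ``n`` cells span the
        longest axis."""
        semi_axes = np.asarray(semi_axes, float)
        L = semi_axes + margin
        h = 2 * L.max() / n
        shape = tuple(int(np.ceil(2 * Li / h)) for Li in L)
        origin = -np.asarray(shape) * h / 2.0

        def inside(pts):
            return np.sum((pts / semi_axes) ** 2, axis=1) < 1.0

        def viscosity(pts):
            inner = semi_axes - gap
            return np.where(np.sum((pts / inner) ** 2, axis=1) < 1.0, eta, eta_pv)

        return cls(origin=origin, shape=shape, h=h, inside=inside, viscosity=viscosity)

    # ------------------------------------------------------------ assembly
    def _face_index(self, a: int) -> np.ndarray:
        return np.arange(self._n_face[a]).reshape(self.face_shape(a)) + int(self._offset[a])

    def _p_index(self) -> np.ndarray:
        return np.arange(int(np.prod(self.shape))).reshape(self.shape) + int(self._offset[-1])

    def _eta_edge(self, a: int, b: int) -> np.ndarray:
        """Viscosity on (a,b)-edges: mean of adjacent cell centres, replicated
        at the grid fringe.  Shape is the cell grid +1 along both a and b."""
        eta = self.eta_center
        for ax in sorted((a, b)):
            pad = [(1, 1) if c == ax else (0, 0) for c in range(self.dim)]
            padded = np.pad(eta, pad, mode="edge")
            lo = tuple(slice(0, -1) if c == ax else slice(None) for c in range(self.dim))
            hi = tuple(slice(1, None) if c == ax else slice(None) for c in range(self.dim))
            eta = 0.5 * (padded[lo] + padded[hi])
        return eta

    def _assemble(self) -> sp.csc_matrix:
        dim, h = self.dim, self.h
        inv_h2 = 1.0 / h**2
        rows, cols, vals = [], [], []

        def add(r, c, v):
            r, c, v = np.broadcast_arrays(r, c, v)
            rows.append(np.asarray(r, int).ravel())
            cols.append(np.asarray(c, int).ravel())
            vals.append(np.asarray(v, float).ravel())

        U = [self._face_index(a) for a in range(dim)]
        P = self._p_index()
        eta_c = self.eta_center

        for a in range(dim):
            act = self.face_active[a]
            fshape = self.face_shape(a)
            I = list(np.indices(fshape))  # face coordinates (ia along axis a)
            diag = np.zeros(fshape)

            # --- normal stress d/dxa [2 eta dua/dxa]; face ia flanks cells
            # ia-1 and ia along axis a
            # cell ia (clamped; the clamp is only ever hit on inactive fringe faces)
            eta_hi = eta_c[tuple(
                np.clip(I[c] if c != a else I[a], 0, self.shape[c] - 1) for c in range(dim)
            )]
            eta_lo = eta_c[tuple(
                np.clip(I[c] if c != a else I[a] - 1, 0, self.shape[c] - 1) for c in range(dim)
            )]
            nbr_hi = _lookup(U[a], [I[c] if c != a else I[a] + 1 for c in range(dim)])
            nbr_lo = _lookup(U[a], [I[c] if c != a else I[a] - 1 for c in range(dim)])
            for nbr, eta_w in ((nbr_hi, eta_hi), (nbr_lo, eta_lo)):
                ok = act & (nbr >= 0)
                add(U[a][ok], nbr[ok], (-2.0 * eta_w * inv_h2)[ok])
                diag += 2.0 * eta_w * inv_h2

            # --- shear stresses d/dxb [eta (dua/dxb + dub/dxa)], b != a
            for b in range(dim):
                if b == a:
                    continue
                eta_e = self._eta_edge(a, b)
                # edges above/below the face along axis b share the face's a-index
                e_up = eta_e[tuple(
                    np.minimum(I[c], np.asarray(eta_e.shape)[c] - 1) if c != b else I[b] + 1
                    for c in range(dim)
                )]
                e_dn = eta_e[tuple(
                    np.minimum(I[c], np.asarray(eta_e.shape)[c] - 1) if c != b else I[b]
                    for c in range(dim)
                )]

                # dua/dxb part.  A missing or inactive neighbour means the
                # no-slip wall runs along the edge between the two faces;
                # mirror the velocity across it (ghost = −u) so the wall
                # shear is second-order at grid-aligned walls instead of the
                # O(1)-inconsistent ghost = 0.
                act_pad = act.astype(int)
                up = _lookup(U[a], [I[c] if c != b else I[b] + 1 for c in range(dim)])
                dn = _lookup(U[a], [I[c] if c != b else I[b] - 1 for c in range(dim)])
                up_act = _lookup(act_pad, [I[c] if c != b else I[b] + 1 for c in range(dim)]) == 1
                dn_act = _lookup(act_pad, [I[c] if c != b else I[b] - 1 for c in range(dim)]) == 1
                for nbr, nbr_ok, eta_w in ((up, up_act, e_up), (dn, dn_act, e_dn)):
                    ok = act & (nbr >= 0) & nbr_ok
                    add(U[a][ok], nbr[ok], (-eta_w * inv_h2)[ok])
                    diag += eta_w * inv_h2
                    # mirrored ghost doubles the diagonal weight at walls
                    wall = act & ~((nbr >= 0) & nbr_ok)
                    diag += np.where(wall, eta_w * inv_h2, 0.0)

                # dub/dxa part: four b-faces at the corners of the (a,b) plane
                def vcoords(da, db):
                    return [
                        I[c] + (da if c == a else (db if c == b else 0))
                        for c in range(dim)
                    ]

                for (da, db), sgn, eta_w in (
                    ((0, 1), -1.0, e_up),   # ub(ia,   ib+1)
                    ((-1, 1), +1.0, e_up),  # ub(ia-1, ib+1)
                    ((0, 0), +1.0, e_dn),   # ub(ia,   ib)
                    ((-1, 0), -1.0, e_dn),  # ub(ia-1, ib)
                ):
                    nbr = _lookup(U[b], vcoords(da, db))
                    ok = act & (nbr >= 0)
                    add(U[a][ok], nbr[ok], (sgn * eta_w * inv_h2)[ok])

            add(U[a][act], U[a][act], diag[act])

            # --- pressure gradient (p(ia) - p(ia-1)) / h
            p_hi = _lookup(P, [I[c] if c != a else I[a] for c in range(dim)])
            p_lo = _lookup(P, [I[c] if c != a else I[a] - 1 for c in range(dim)])
            for nbr, sgn in ((p_hi, 1.0), (p_lo, -1.0)):
                ok = act & (nbr >= 0)
                add(U[a][ok], nbr[ok], sgn / h)

            # inactive faces pinned to zero
            add(U[a][~act], U[a][~act], 1.0)

        # --- continuity on active cells, one cell pinned to fix the gauge
        pin_flat = int(np.flatnonzero(self.p_active.ravel())[0]) \
            if self.p_active.any() else None
        if pin_flat is None:
            raise ValueError("no active fluid cells in domain")
        p_act = self.p_active.ravel().copy()
        p_act[pin_flat] = False
        p_act = p_act.reshape(self.shape)

        for a in range(dim):
            hi = tuple(slice(1, None) if b == a else slice(None) for b in range(dim))
            lo = tuple(slice(0, -1) if b == a else slice(None) for b in range(dim))
            add(P[p_act], U[a][hi][p_act], 1.0 / h)
            add(P[p_act], U[a][lo][p_act], -1.0 / h)
        add(P[~p_act], P[~p_act], 1.0)

        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        )
        return A.tocsc()

    @property
    def matrix(self) -> sp.csc_matrix:
        if self._A is None:
            self._A = self._assemble()
        return self._A

    @property
    def lu(self):
        if self._lu is None:
            self._lu = splu(self.matrix)
        return self._lu


def solve_stokes(domain: FluidDomain, f, tol: float = 1e-8) -> VelocityField:
    """Solve the masked variable-viscosity Stokes system.

    ``f`` is the force density as a tuple of staggered face arrays (force per
    volume).  Returns velocity (and pressure).  The factored solve's residual
    is checked against ``tol`` relative to the forcing and an error is raised
    on failure.
    """
    f = tuple(np.asarray(fi, float) for fi in f)
    for a in range(domain.dim):
        if f[a].shape != domain.face_shape(a):
            raise ValueError(
                f"force component {a} has shape {f[a].shape}, expected "
                f"{domain.face_shape(a)}"
            )
        if not np.all(np.isfinite(f[a])):
            raise ValueError("force density contains non-finite values")

    rhs = np.zeros(domain.n_dof)
    for a in range(domain.dim):
        vals = np.where(domain.face_active[a], f[a], 0.0)
        rhs[int(domain._offset[a]):int(domain._offset[a + 1])] = vals.ravel()

    x = domain.lu.solve(rhs)

    scale = float(np.abs(rhs).max())
    if scale > 0.0:
        resid = float(np.abs(domain.matrix @ x - rhs).max())
        if resid > tol * scale:
            raise RuntimeError(
                f"Stokes solve residual {resid:.3e} exceeds {tol:.1e} × |f| = "
                f"{tol * scale:.3e}"
            )

    comps = tuple(
        x[int(domain._offset[a]):int(domain._offset[a + 1])].reshape(domain.face_shape(a))
        for a in range(domain.dim)
    )
    pressure = x[int(domain._offset[-1]):].reshape(domain.shape)
    return VelocityField(components=comps, pressure=pressure)


def discrete_divergence(domain: FluidDomain, vel: VelocityField) -> np.ndarray:
    """Cell-centred divergence using the solver's own stencil; zero outside
    the fluid region."""
    div = np.zeros(domain.shape)
    for a in range(domain.dim):
        c = vel.components[a]
        hi = tuple(slice(1, None) if b == a else slice(None) for b in range(domain.dim))
        lo = tuple(slice(0, -1) if b == a else slice(None) for b in range(domain.dim))
        div += (c[hi] - c[lo]) / domain.h
    div[~domain.p_active] = 0.0
    return div
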