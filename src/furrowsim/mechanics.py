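"""Elastic and active (contractile) forces on the spring-network membranes.

Membranes are linearly elastic: each spring exerts a Hookean restoring force
``k (ℓ − ℓ0)`` along its axis.  Myosin activity is modelled as contractile
tension added on top: a constitutive tension ``σ0`` on every membrane, plus a
ramped tension on the apical and lateral membranes of the mesodermal cells
that rises linearly from 0 to ``σ_max`` over the ramp duration ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import APICAL, LATERAL, CLASS_CODES, EmbryoGeometry

__all__ = [
    "MembraneMaterial",
    "ForceProtocol",
    "spring_constants_from_material",
    "elastic_forces",
    "active_forces",
    "perivitelline_penalty_forces",
    "vitelline_contact_forces",
    "total_forces",
    "elastic_energy",
]

# effective Poisson ratio of an equal-stiffness triangular spring lattice
TRIANGULAR_LATTICE_POISSON = 1.0 / 3.0


@dataclass(frozen=True)
class MembraneMaterial:
    """Linear-elastic plate material: Young's modulus E (Pa), Poisson ratio ν,
    thickness h (µm)."""

    young_modulus: float
    poisson_ratio: float = TRIANGULAR_LATTICE_POISSON
    thickness: float = 1.0

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class ForceProtocol:
    """Contractile-stress protocol.

    ``sigma0`` is a small constitutive tension on every membrane.  Mesodermal
    apical/lateral membranes additionally receive a tension that ramps from 0
    to ``sigma_max`` over ``ramp_duration`` (``linear`` mode) or is applied at
    full strength immediately (``instantaneous`` mode).  Tensions are force
    per unit depth in 2D (model units) or force per unit length in 3D.
    """

    sigma0: float = 0.0
    sigma_max: float = 0.0
    ramp_duration: float = 1.0
    ramp_mode: str = "linear"
    target_classes: tuple[str, ...] = ("apical", "lateral")
    #: per-class weights on the ramped mesodermal tension.  Lateral tension
    #: squeezes the incompressible cells radially and is the volume-dependent
    #: motor that pushes the mesodermal plate into the yolk; apical tension
    #: constricts the outer surface.  The relative magnitudes are not pinned
    #: by the printed text and are model parameters.
    lateral_fraction: float = 1.0
    apical_fraction: float = 0.3
    #: contractile tension saturates once a segment is compressed below this
    #: fraction of its rest length (tension ∝ current length there).  Pure
    #: constant tension would collapse segments to zero length, a physical
    #: and numerical singularity; the cutoff mimics motor-density saturation.
    tension_cutoff_frac: float = 0.5
    #: stiffness of the perivitelline volume-conservation penalty (force per
    #: unit relative volume change).  The perivitelline space is a thin
    #: incompressible layer whose volume is conserved; a soft global penalty
    #: on the enclosed-area change of the embryo's outer surface enforces
    #: this without resolving a micron-scale lubrication film on the grid.
    #: 0 disables the constraint.
    peri_stiffness: float = 0.0
    #: one-sided vitelline contact stiffness (force per µm of outward
    #: excursion, per node).  The embryo surface is pressed against the
    #: eggshell with only a micron-scale fluid film between them; nodes
    #: moving radially beyond their initial apical radius are pushed back.
    #: This forbids the unphysical outward bulging that would otherwise let
    #: the surface trade area with the (numerically widened) perivitelline
    #: band.  0 disables contact.
    wall_stiffness: float = 0.0
    #: contact engages this many µm beyond the initial apical radius.  The
    #: offset is the effective perivitelline film budget: the area swept by
    #: outward surface motion before contact is the only volume available to
    #: an invagination, which caps wide craters while leaving narrow folds
    #: (an order of magnitude less area per unit depth) unaffected.
    wall_slack: float = 1.5

    def __post_init__(self):
        if self.sigma0 < 0 or self.sigma_max < 0:
            raise ValueError("tensions must be non-negative")
        if self.ramp_mode not in ("linear", "instantaneous"):
            raise ValueError(f"unknown ramp_mode {self.ramp_mode!r}")
        if self.ramp_mode == "linear" and self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive for a linear ramp")
        unknown = set(self.target_classes) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown membrane classes {unknown}")

    def ramp_value(self, t: float) -> float:
        """Mesodermal added tension at time ``t``."""
        if self.ramp_mode == "instantaneous":
            return self.sigma_max
        return self.sigma_max * min(max(t, 0.0) / self.ramp_duration, 1.0)

    def rescaled(self, ramp_multiplier: float) -> "ForceProtocol":
        """Same protocol with the ramp slowed by ``ramp_multiplier``."""
        return ForceProtocol(
            sigma0=self.sigma0,
            sigma_max=self.sigma_max,
            ramp_duration=self.ramp_duration * ramp_multiplier,
            ramp_mode=self.ramp_mode,
            target_classes=self.target_classes,
            lateral_fraction=self.lateral_fraction,
            apical_fraction=self.apical_fraction,
            tension_cutoff_frac=self.tension_cutoff_frac,
            peri_stiffness=self.peri_stiffness,
            wall_stiffness=self.wall_stiffness,
            wall_slack=self.wall_slack,
        )

    def ramp_weights(self, geometry: EmbryoGeometry) -> np.ndarray:
        """Per-edge multiplier on the ramped mesodermal tension: 1 on targeted
        apical/basal classes, ``lateral_fraction`` on targeted laterals, 0
        elsewhere and outside the mesoderm."""
        w = np.zeros(len(geometry.edges))
        frac = {LATERAL: self.lateral_fraction, APICAL: self.apical_fraction}
        for name in self.target_classes:
            code = CLASS_CODES[name]
            amp = frac.get(code, 1.0)
            w[(geometry.edge_class == code) & geometry.edge_mesoderm] = amp
        return w

    def saturation(self, geometry: EmbryoGeometry, length: np.ndarray) -> np.ndarray:
        """Per-edge factor in [0, 1] scaling *active* tension: 1 above the
        cutoff length, proportional to current length below it."""
        if self.tension_cutoff_frac <= 0:
            return np.ones_like(length)
        cut = self.tension_cutoff_frac * geometry.rest_length
        return np.clip(length / cut, None, 1.0)

    def to_dict(self) -> dict:
        return {
            "sigma0": self.sigma0,
            "sigma_max": self.sigma_max,
            "ramp_T": self.ramp_duration,
            "ramp_mode": self.ramp_mode,
            "target_classes": list(self.target_classes),
            "lateral_fraction": self.lateral_fraction,
            "apical_fraction": self.apical_fraction,
            "tension_cutoff_frac": self.tension_cutoff_frac,
            "peri_stiffness": self.peri_stiffness,
            "wall_stiffness": self.wall_stiffness,
            "wall_slack": self.wall_slack,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceProtocol":
        return cls(
            sigma0=d.get("sigma0", 0.0),
            sigma_max=d.get("sigma_max", 0.0),
            ramp_duration=d.get("ramp_T", 1.0),
            ramp_mode=d.get("ramp_mode", "linear"),
            target_classes=tuple(d.get("target_classes", ("apical", "lateral"))),
            lateral_fraction=d.get("lateral_fraction", 1.0),
            apical_fraction=d.get("apical_fraction", 0.3),
            tension_cutoff_frac=d.get("tension_cutoff_frac", 0.5),
            peri_stiffness=d.get("peri_stiffness", 0.0),
            wall_stiffness=d.get("wall_stiffness", 0.0),
            wall_slack=d.get("wall_slack", 1.5),
        )


def spring_constants_from_material(
    material: MembraneMaterial,
    geometry: EmbryoGeometry,
    allow_poisson_mismatch: bool = False,
) -> np.ndarray:
    """Per-edge spring stiffnesses reproducing the plate material's
    small-strain response.

    2D chains (plane cross-section, per unit depth): ``k = E·h / ℓ0``.

    3D triangulated plates use the equal-spring correspondence for a uniform
    triangular lattice, ``k = √3·E·h / 2``, whose effective sheet moduli are
    ``E_2D = 2k/√3`` with lattice-fixed Poisson ratio ν = 1/3.  Requesting a
    different ν without ``allow_poisson_mismatch`` raises.
    """
    if geometry.dim == 2:
        return material.young_modulus * material.thickness / geometry.rest_length
    if not np.isclose(material.poisson_ratio, TRIANGULAR_LATTICE_POISSON):
        if not allow_poisson_mismatch:
            raise ValueError(
                "a uniform triangular spring lattice fixes ν = 1/3; pass "
                "allow_poisson_mismatch=True to proceed with mismatched ν"
            )
    k = np.sqrt(3.0) / 2.0 * material.young_modulus * material.thickness
    return np.full(len(geometry.edges), k)


def _edge_geometry(geometry: EmbryoGeometry, positions: np.ndarray):
    i, j = geometry.edges[:, 0], geometry.edges[:, 1]
    d = positions[j] - positions[i]
    length = np.linalg.norm(d, axis=1)
    if np.any(length <= 0.0):
        bad = int(np.argmin(length))
        raise ValueError(f"edge {bad} has coincident endpoints (zero length)")
    return i, j, d, length


def _accumulate(n_nodes: int, dim: int, i, j, pair_force: np.ndarray) -> np.ndarray:
    """Scatter per-edge forces ±pair_force onto endpoint nodes."""
    out = np.zeros((n_nodes, dim))
    for a in range(dim):
        out[:, a] = np.bincount(i, weights=pair_force[:, a], minlength=n_nodes)
        out[:, a] -= np.bincount(j, weights=pair_force[:, a], minlength=n_nodes)
    return out


def elastic_forces(geometry: EmbryoGeometry, positions: np.ndarray) -> np.ndarray:
    """Hookean spring forces, (N, dim).  Force on node i from edge (i, j) is
    ``k (ℓ − ℓ0) d̂`` (pulls i toward j when stretched)."""
    i, j, d, length = _edge_geometry(geometry, positions)
    tension = geometry.stiffness * (length - geometry.rest_length)
    pair = (tension / length)[:, None] * d
    return _accumulate(len(positions), geometry.dim, i, j, pair)


def elastic_energy(geometry: EmbryoGeometry, positions: np.ndarray) -> float:
    """Quadratic spring energy ½ Σ k (ℓ − ℓ0)²; elastic_forces is −∇ of this."""
    length = geometry.edge_lengths(positions)
    return float(0.5 * np.sum(geometry.stiffness * (length - geometry.rest_length) ** 2))


def active_forces(
    geometry: EmbryoGeometry,
    protocol: ForceProtocol,
    t: float,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Contractile tension forces at time ``t``, (N, dim).

    Every edge carries tension ``σ0``; targeted mesodermal edges carry
    ``σ0 + ramp_value(t)`` weighted by their class fraction.  Tension pulls
    the edge endpoints together independent of strain, except that it
    saturates (∝ current length) once a segment is compressed below the
    protocol's cutoff fraction of its rest length.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    pos = geometry.nodes if positions is None else positions
    i, j, d, length = _edge_geometry(geometry, pos)
    sat = protocol.saturation(geometry, length)
    tension = protocol.sigma0 * sat
    tension += protocol.ramp_value(t) * protocol.ramp_weights(geometry) * sat
    pair = (tension / length)[:, None] * d
    return _accumulate(len(pos), geometry.dim, i, j, pair)


def perivitelline_penalty_forces(
    geometry: EmbryoGeometry,
    positions: np.ndarray,
    stiffness: float,
) -> np.ndarray:
    """Restoring forces conserving the perivitelline volume.

    The perivitelline measure is the vitelline disk minus the area enclosed
    by the embryo's outer (apical) boundary loop, so conserving it is
    equivalent to conserving the enclosed area A.  The penalty energy
    ``U = ½ k (A − A0)² / A0`` yields shoelace-gradient forces on the outer
    boundary nodes; its stiffness sets the pressure the thin incompressible
    layer exerts per unit relative volume change.
    """
    out = np.zeros_like(positions)
    if stiffness == 0.0:
        return out
    loop = geometry.outer_boundary_loop()
    ref = geometry.nodes[loop]
    a0 = 0.5 * np.sum(ref[:, 0] * np.roll(ref[:, 1], -1) - np.roll(ref[:, 0], -1) * ref[:, 1])
    cur = positions[loop]
    a = 0.5 * np.sum(cur[:, 0] * np.roll(cur[:, 1], -1) - np.roll(cur[:, 0], -1) * cur[:, 1])
    coef = -stiffness * (a - a0) / a0
    # ∂A/∂x_i = ½(y_{i+1} − y_{i−1}),  ∂A/∂y_i = ½(x_{i−1} − x_{i+1})
    gx = 0.5 * (np.roll(cur[:, 1], -1) - np.roll(cur[:, 1], 1))
    gy = 0.5 * (np.roll(cur[:, 0], 1) - np.roll(cur[:, 0], -1))
    np.add.at(out[:, 0], loop, coef * gx)
    np.add.at(out[:, 1], loop, coef * gy)
    return out


def vitelline_contact_forces(
    geometry: EmbryoGeometry,
    positions: np.ndarray,
    stiffness: float,
    slack: float = 0.0,
) -> np.ndarray:
    """One-sided radial contact with the vitelline shell.

    Nodes beyond the initial apical radius (vitelline radius minus the
    perivitelline film) receive a linear inward restoring force.
    """
    out = np.zeros_like(positions)
    if stiffness == 0.0:
        return out
    r_contact = geometry.vitelline_radius - geometry.perivitelline_gap + slack
    r = np.linalg.norm(positions, axis=1)
    excess = r - r_contact
    hit = excess > 0
    if np.any(hit):
        out[hit] = -stiffness * (excess[hit] / r[hit])[:, None] * positions[hit]
    return out


def total_forces(
    geometry: EmbryoGeometry,
    protocol: ForceProtocol,
    t: float,
    positions: np.ndarray,
) -> np.ndarray:
    """Elastic + active force at every solid node (IBM step 1)."""
    i, j, d, length = _edge_geometry(geometry, positions)
    sat = protocol.saturation(geometry, length)
    tension = geometry.stiffness * (length - geometry.rest_length)
    tension += (protocol.sigma0 + protocol.ramp_value(t) * protocol.ramp_weights(geometry)) * sat
    pair = (tension / length)[:, None] * d
    out = _accumulate(len(positions), geometry.dim, i, j, pair)
    if protocol.peri_stiffness and geometry.dim == 2:
        out += perivitelline_penalty_forces(geometry, positions, protocol.peri_stiffness)
    if protocol.wall_stiffness:
        out += vitelline_contact_forces(
            geometry, positions, protocol.wall_stiffness, protocol.wall_slack
        )
    return out
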