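"""The 2D ventral-furrow study: one frozen configuration, five variants.

The 2D model runs in arbitrary units (the membrane stretch modulus and the
cytoplasmic viscosity both set to 1); geometry is in µm.  The five variants
mirror the perturbation matrix of the cross-section model:

* ``baseline`` — closed cells (wild type),
* ``no_basal`` — basal membranes removed (anillin knockdown),
* ``low_viscosity`` — closed cells, cytoplasm/yolk viscosity ÷ 100,
* ``no_basal_low_viscosity`` — both perturbations,
* ``no_basal_slow_ramp`` — open cells, contractility ramped 33× more slowly.

Time steps scale with viscosity (the explicit stability limit is
proportional to η), which also preserves the exact viscosity↔ramp-time
rescaling equivalence of Stokes flow.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import EmbryoGeometry, build_cross_section_2d, remove_basal_membranes
from .ibm import SimulationParams, Trajectory, run_simulation
from .mechanics import ForceProtocol
from .stokes import FluidDomain

__all__ = ["StudyConfig", "DEFAULT_STUDY", "VARIANTS", "run_variant"]

VARIANTS = (
    "baseline",
    "no_basal",
    "low_viscosity",
    "no_basal_low_viscosity",
    "no_basal_slow_ramp",
)

SLOW_RAMP_FACTOR = 33.0
LOW_VISCOSITY_FACTOR = 0.01


@dataclass(frozen=True)
class StudyConfig:
    """Frozen desk-scale study conditions for the 2D cross-section model."""

    # geometry (µm)
    n_cells: int = 80
    n_mesoderm: int = 16
    radius: float = 90.0
    cell_height: float = 35.0
    gap: float = 8.0
    spacing: float = 1.3
    stretch_modulus: float = 1.0
    # fluid
    grid_n: int = 80
    eta: float = 1.0
    eta_pv_ratio: float = 1e-3
    # force protocol
    sigma0: float = 0.01
    sigma_max: float = 4.0
    apical_fraction: float = 1.0
    lateral_fraction: float = 0.15
    ramp_T: float = 20.0
    # stepping
    dt: float = 0.06
    t_max: float = 500.0
    sample_every: int = 50

    def geometry(self, open_basal: bool = False) -> EmbryoGeometry:
        g = build_cross_section_2d(
            n_cells=self.n_cells,
            radius=self.radius,
            cell_height=self.cell_height,
            gap=self.gap,
            n_mesoderm=self.n_mesoderm,
            spacing=self.spacing,
            stretch_modulus=self.stretch_modulus,
        )
        return remove_basal_membranes(g) if open_basal else g

    def domain(self, eta_factor: float = 1.0) -> FluidDomain:
        return FluidDomain.disk(
            radius=self.radius,
            gap=self.gap,
            eta=self.eta * eta_factor,
            eta_pv=self.eta * self.eta_pv_ratio * eta_factor,
            n=self.grid_n,
        )

    def protocol(
        self, ramp_multiplier: float = 1.0, ramp_mode: str = "linear"
    ) -> ForceProtocol:
        return ForceProtocol(
            sigma0=self.sigma0,
            sigma_max=self.sigma_max,
            ramp_duration=self.ramp_T * ramp_multiplier,
            ramp_mode=ramp_mode,
            apical_fraction=self.apical_fraction,
            lateral_fraction=self.lateral_fraction,
        )

    def params(
        self, eta_factor: float = 1.0, ramp_multiplier: float = 1.0
    ) -> SimulationParams:
        # at reduced viscosity the dynamics (and the stability limit) speed
        # up 100-fold, so the run only needs to cover the ramp plus a short
        # mechanical relaxation; at full viscosity the plateau rule governs
        if eta_factor < 1.0:
            t_max = 1.05 * self.ramp_T * ramp_multiplier
            min_time = self.ramp_T * ramp_multiplier
        else:
            t_max = self.t_max * ramp_multiplier
            min_time = 2.0 * self.ramp_T * ramp_multiplier
        return SimulationParams(
            dt=self.dt * eta_factor,
            t_max=t_max,
            sample_every=self.sample_every,
            min_time=min_time,
        )


DEFAULT_STUDY = StudyConfig()

_VARIANT_SETTINGS = {
    "baseline": dict(open_basal=False, eta_factor=1.0, ramp_multiplier=1.0),
    "no_basal": dict(open_basal=True, eta_factor=1.0, ramp_multiplier=1.0),
    "low_viscosity": dict(open_basal=False, eta_factor=LOW_VISCOSITY_FACTOR,
                          ramp_multiplier=1.0),
    "no_basal_low_viscosity": dict(open_basal=True, eta_factor=LOW_VISCOSITY_FACTOR,
                                   ramp_multiplier=1.0),
    "no_basal_slow_ramp": dict(open_basal=True, eta_factor=1.0,
                               ramp_multiplier=SLOW_RAMP_FACTOR),
}


def run_variant(
    name: str,
    config: StudyConfig = DEFAULT_STUDY,
    ramp_mode: str = "linear",
) -> Trajectory:
    """Run one variant of the perturbation matrix and return its trajectory."""
    if name not in _VARIANT_SETTINGS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    s = _VARIANT_SETTINGS[name]
    geometry = config.geometry(open_basal=s["open_basal"])
    domain = config.domain(eta_factor=s["eta_factor"])
    protocol = config.protocol(ramp_multiplier=s["ramp_multiplier"], ramp_mode=ramp_mode)
    params = config.params(
        eta_factor=s["eta_factor"], ramp_multiplier=s["ramp_multiplier"]
    )
    return run_simulation(geometry, protocol, params, domain)
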