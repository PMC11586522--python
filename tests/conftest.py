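import numpy as np
import pytest

from furrowsim.geometry import build_cross_section_2d, remove_basal_membranes
from furrowsim.stokes import FluidDomain


@pytest.fixture(scope="session")
def ring4():
    """Four-cell toy ring, one spring per membrane."""
    return build_cross_section_2d(
        n_cells=4, radius=90.0, cell_height=35.0, gap=8.0,
        nodes_per_membrane=1, n_mesoderm=1,
    )


@pytest.fixture(scope="session")
def ring80():
    """Default-scale embryo cross-section."""
    return build_cross_section_2d()


@pytest.fixture(scope="session")
def ring80_open(ring80):
    return remove_basal_membranes(ring80)


@pytest.fixture(scope="session")
def small_disk_domain():
    """Coarse vitelline-disk fluid domain for fast coupling tests."""
    return FluidDomain.disk(radius=90.0, gap=8.0, eta=1.0, eta_pv=1e-3, n=48)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
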