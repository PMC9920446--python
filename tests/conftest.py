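import numpy as np
import pytest
from hypothesis import settings

from mitchain import (ConductivityGrid, ScanGeometry, basis_currents,
                      make_phantom)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    """Default scanner geometry: D = 16 cm, 20x20 sheet, receivers at 10 cm."""
    return ScanGeometry()


@pytest.fixture(scope="session")
def close_geometry():
    """Receivers at 5 cm — the sharpest contactless preset."""
    return ScanGeometry(z_receiver=0.05)


@pytest.fixture(scope="session")
def reduced_geometry():
    """10x10-pixel reduced instance (20 cm sheet, 100 scan samples)."""
    return ScanGeometry(sheet_size=(0.2, 0.2), n_scan=100)


@pytest.fixture(scope="session")
def homogeneous():
    return make_phantom("homogeneous")


@pytest.fixture(scope="session")
def three_level():
    return make_phantom("three-level")


@pytest.fixture(scope="session")
def basis_fields(three_level, geometry):
    """Solved phi/psi eddy fields of the three-level phantom."""
    return basis_currents(three_level, geometry)


@pytest.fixture
def small_grid():
    """3x3-cell homogeneous grid (the 16-node, 24-edge, 9-loop example)."""
    return ConductivityGrid(np.full((3, 3), 0.5), cell_size=0.02,
                            origin=(-0.03, -0.03))
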