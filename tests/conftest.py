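import numpy as np
import pytest

from gridci.geometry import WaveBasis, hex_mesh, make_unit_cell
from gridci.optimise import GridPhaseModel


@pytest.fixture(scope="session")
def cell():
    return make_unit_cell(WaveBasis())


@pytest.fixture(scope="session")
def mesh32(cell):
    return hex_mesh(32, cell)


@pytest.fixture(scope="session")
def ci7(cell):
    """A converged 7-cell conformal-isometry fit (shared across tests)."""
    return GridPhaseModel(7, "ci").fit(steps=3000, seed=0)


@pytest.fixture(scope="session")
def ci100():
    """A converged 100-cell conformal-isometry fit (shared across tests)."""
    return GridPhaseModel(100, "ci").fit(steps=500, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
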