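import numpy as np
import pytest

from veinadapt.geometry import build_basic_geometry, seed_cells
from veinadapt.params import MechanicsParams, RemodelingParams


@pytest.fixture(scope="session")
def vessel():
    """Standard implantation geometry on a moderately coarse grid."""
    return build_basic_geometry(0.24, 0.28, 0.30, h=0.0075,
                                membrane_stiffness=0.02)


@pytest.fixture(scope="session")
def seeded(vessel):
    pop, ecm = seed_cells(vessel, 0.25, rng_seed=1)
    return pop, ecm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mech_params():
    return MechanicsParams()


@pytest.fixture(scope="session")
def remod_params():
    return RemodelingParams()
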