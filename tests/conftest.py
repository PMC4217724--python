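import numpy as np
import pytest

from stentdeg.datasets import load_table1
from stentdeg.material import build_curve_library, default_pristine_curve
from stentdeg.stent import (
    StentGeometry,
    new_state,
    release_recoil,
    simulate_crimp,
    simulate_expansion,
)

#: Degradation-degree grid of the packaged tensile fixture,
#: (pre_stretch, time_days) -> printed degree.
TABLE1_DEGREES = {
    (0.0, 3): 0.1,
    (0.0, 10): 0.143491,
    (0.0, 20): 0.140257,
    (0.0, 30): 0.189641,
    (0.2, 3): 0.18003,
    (0.2, 10): 0.545436,
    (0.2, 20): 0.59842,
    (0.2, 30): 0.736638,
    (0.4, 3): 0.48152,
    (0.4, 10): 0.492528,
    (0.4, 20): 0.701681,
    (0.4, 30): 0.776536,
}


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def pristine_curve():
    return default_pristine_curve()


@pytest.fixture(scope="session")
def curve_library(pristine_curve):
    return build_curve_library(pristine_curve)


@pytest.fixture(scope="session")
def small_geometry():
    # coarse discretisation keeps the solver tests fast; the mechanics
    # checks are about behaviour, not mesh convergence
    return StentGeometry(elements_per_strut=4, elements_per_bridge=1)


@pytest.fixture(scope="session")
def deployed_state_master(small_geometry, curve_library):
    """Crimped, recoiled, expanded and re-recoiled scaffold (built once)."""
    state = new_state(small_geometry, curve_library)
    simulate_crimp(state, 1.5, n_inc=30)
    release_recoil(state)
    simulate_expansion(state, 3.2, n_inc=20)
    release_recoil(state)
    return state


@pytest.fixture
def deployed_state(deployed_state_master):
    return deployed_state_master.copy()
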