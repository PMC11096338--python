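import numpy as np
import pytest

from vesihybrid import make_sphere_mesh, make_box_mesh


@pytest.fixture(scope="session")
def coarse_sphere():
    """0.5 um ball, ~120 nm tets (a few hundred elements)."""
    return make_sphere_mesh(0.5e-6, 120e-9, seed=1)


@pytest.fixture(scope="session")
def fine_sphere():
    """0.5 um ball, ~45 nm tets (vesicles overlap several tets)."""
    return make_sphere_mesh(0.5e-6, 45e-9, seed=2)


@pytest.fixture(scope="session")
def small_box():
    return make_box_mesh([0.3e-6, 0.3e-6, 0.3e-6], 80e-9, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
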