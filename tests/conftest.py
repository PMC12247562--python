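import numpy as np
import pytest

from netgrowth.surface import make_sphere_mesh
from netgrowth.synthetic import make_sphere_parcellation


@pytest.fixture(scope="session")
def small_mesh():
    return make_sphere_mesh(162)


@pytest.fixture(scope="session")
def small_parc(small_mesh):
    return make_sphere_parcellation(162, 4, 2, seed=11, mesh=small_mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240408)
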