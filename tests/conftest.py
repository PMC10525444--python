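import numpy as np
import pytest

from corneosim.geometry import BiconicParams
from corneosim.surfaces import make_biconic_surface

#: reference pre-op biconic parameters (anterior healthy / KC, posterior healthy)
HEALTHY_ANT = BiconicParams(7.37, 7.62, -0.25, -0.10)
KC_ANT = BiconicParams(6.15, 7.24, -1.55, 1.33)
HEALTHY_POST = BiconicParams(7.91, 7.97, 0.63, 0.37)


@pytest.fixture(scope="session")
def healthy_surface():
    return make_biconic_surface(HEALTHY_ANT, 9.0, 0.1, label="healthy pre")


@pytest.fixture(scope="session")
def sphere_surface():
    return make_biconic_surface(BiconicParams(7.5, 7.5, 0.0, 0.0), 8.0, 0.1,
                                label="sphere R7.5")


@pytest.fixture
def rng():
    return np.random.default_rng(20230827)
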