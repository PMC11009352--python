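import numpy as np
import pytest

from vaspdrop.geometry import Confinement, build_icosphere


@pytest.fixture(scope="session")
def unit_sphere():
    return Confinement.sphere(1.0)


@pytest.fixture(scope="session")
def icosphere_unit():
    """4x-subdivided icosphere at the reference droplet radius."""
    return build_icosphere(1.0, 4)


@pytest.fixture(scope="session")
def icosphere_desk():
    return build_icosphere(0.5, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
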