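import numpy as np
import pytest

from stochtissue import PathwayParams, ProtrusionSpec, build_hex_lattice


@pytest.fixture(scope="session")
def default_params() -> PathwayParams:
    """Reference pathway parameters of the static-pattern experiment."""
    return PathwayParams()


@pytest.fixture(scope="session")
def hex10():
    return build_hex_lattice(10, 10)


@pytest.fixture(scope="session")
def isotropic_spec():
    return ProtrusionSpec(length=3.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
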