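import numpy as np
import pytest

from papsim.simcore import GeometryConfig, build_geometry


@pytest.fixture(scope="session")
def model():
    """Default synaptic environment, coarse ECS integration (tests that need
    the calibrated 5-nm value integrate it themselves)."""
    return build_geometry(GeometryConfig(voxel_pitch=20.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
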