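import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emvalid as ev

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def helix_signal_map():
    """Gaussian-atom rendering of a 12-residue ideal helix on a 32³ grid."""
    spec = ev.FixtureSpec(shape=(32, 32, 32), sigma=1.5)
    model = ev.helix_trace(12, center=(16.0, 16.0, 8.0))
    return ev.gaussian_atom_map(model, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def random_map(rng):
    return ev.DensityMap(rng.normal(size=(16, 16, 16)), voxel_size=1.05)
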