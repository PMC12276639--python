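import numpy as np
import pytest

from radstab.synthetic import EllipsoidShells, PhantomConfig, simulate_phantom_pair


@pytest.fixture(scope="session")
def phantom_pair():
    """Default 48^3 phantom: nine maps + CET/NEL/necrosis labelmap."""
    return simulate_phantom_pair(PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def small_phantom_pair():
    """Quick 24^3 phantom for I/O and smoke tests."""
    cfg = PhantomConfig(
        grid_shape=(24, 24, 24),
        roi_geometry=EllipsoidShells(
            center=(11.5, 11.5, 11.5),
            necrosis_radii=(3.0, 3.0, 3.0),
            cet_radii=(6.0, 6.0, 6.0),
            nel_radii=(10.0, 10.0, 10.0),
        ),
        seed=7,
    )
    return simulate_phantom_pair(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
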