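import numpy as np
import pytest

from macmind import PhantomConfig, Volume, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_volume(rng):
    return Volume(data=rng.random((9, 9, 9)))


@pytest.fixture(scope="session")
def small_phantom():
    """One small, quickly generated phantom case shared across tests."""
    return generate_phantom(
        PhantomConfig(size=(24, 24, 20), seed=11, amplitude=2.0, smoothness=4.0)
    )


@pytest.fixture(scope="session")
def aligned_phantom():
    """Phantom with zero deformation (modalities share the exact geometry)."""
    return generate_phantom(PhantomConfig(size=(24, 24, 20), seed=12, amplitude=0.0))
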