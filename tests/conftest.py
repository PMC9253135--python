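import numpy as np
import pytest

from geobia.scene import default_appearance, default_scheme, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 default scene shared across tests."""
    return generate_scene(
        default_scheme(), default_appearance(), 128, 128, 20, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
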