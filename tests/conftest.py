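import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_byte_objects():
    """Seven seeded random byte strings of varying length and entropy."""
    rng = np.random.default_rng(7)
    objs = []
    for i in range(7):
        n = int(rng.integers(30, 150))
        if i % 2:
            objs.append(bytes(rng.integers(0, 256, n, dtype=np.uint8)))
        else:
            objs.append(bytes([i * 3 % 256]) * n)
    return objs


@pytest.fixture(scope="session")
def cell_scene():
    from csfcluster import cell_image

    return cell_image(n_cells=6, size=(160, 160), seed=3)
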