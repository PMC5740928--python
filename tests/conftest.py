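import numpy as np
import pytest

from ffirst.descriptor import MultiScaleConfig
from ffirst.patterns import enumerate_orbits


@pytest.fixture(scope="session")
def table8():
    return enumerate_orbits(8)


@pytest.fixture(scope="session")
def config_full():
    return MultiScaleConfig()


@pytest.fixture(scope="session")
def config_uniform():
    return MultiScaleConfig(mode="uniform", plus=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def disk_mask(n: int, margin: int = 3) -> np.ndarray:
    yy, xx = np.indices((n, n))
    c = (n - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= (n // 2 - margin) ** 2
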