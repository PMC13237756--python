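import numpy as np
import pytest

from restalpha.geometry import build_default_layout, nearest_neighbors
from restalpha.simulate import GenerativeParams


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture(scope="session")
def graph(layout):
    return nearest_neighbors(layout, 4)


@pytest.fixture
def quiet_params():
    """Noise-free generative settings: the linear predictor is exact."""
    return GenerativeParams(
        sigma_noise=0.0,
        sigma_participant=0.0,
        background_ratio=0.0,
        artifact_rate=0.0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
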