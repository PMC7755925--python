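import numpy as np
import pytest

from leupsim.model import Domain, ModelParams, ParticleState


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def domain():
    return Domain(L=20.0)


@pytest.fixture
def params():
    return ModelParams()


def random_state(rng, n, L, t=0.0, speed_high=1.0):
    """Uniform-random valid particle state inside a box of side L."""
    return ParticleState(
        t=t,
        positions=rng.uniform(0.0, L, size=(n, 2)),
        orientations=rng.uniform(0.0, 2 * np.pi, size=n),
        speeds=rng.uniform(0.0, speed_high, size=n),
    )
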