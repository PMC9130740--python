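import numpy as np
import pytest

from nbrlifespan.events import DEFAULT_N_VOLUMES, DEFAULT_TR, generate_paradigm

TR = DEFAULT_TR
N_VOLUMES = DEFAULT_N_VOLUMES


@pytest.fixture(scope="session")
def schedule():
    """Full-size study paradigm: 128 trials on a 2 s grid, SOAs 2–26 s."""
    return generate_paradigm(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
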