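import numpy as np
import pytest

from bregmri import synthetic as syn


@pytest.fixture(scope="session")
def small_phantom() -> syn.Phantom:
    """64x64 default-design phantom with one centered lesion."""
    return syn.make_phantom(64, 64, [syn.LesionSpec((32, 32), 5, 60)], seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
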