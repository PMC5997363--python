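import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


def rademacher(rng, *shape):
    return rng.choice(np.array([-1.0, 1.0]), size=shape)
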