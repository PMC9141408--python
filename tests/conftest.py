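import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_batch(rng):
    """A generic small Gaussian batch."""
    return rng.standard_normal((40, 4))


@pytest.fixture
def contaminated_batch(rng):
    """30 honest N(0, I) rows plus 4 rows shifted far away."""
    x = rng.standard_normal((34, 3))
    x[:4] += 50.0
    return x, np.arange(34) < 4
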