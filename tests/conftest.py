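import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_physical_stokes(rng, n=1, dop_max=1.0):
    """Random physical Stokes vectors with S0 = 1 and DOP <= dop_max."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    dop = rng.uniform(0.0, dop_max, size=(n, 1))
    out = np.concatenate([np.ones((n, 1)), v * dop], axis=1)
    return out[0] if n == 1 else out
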