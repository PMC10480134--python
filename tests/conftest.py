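import numpy as np
import pytest

from radiomap.features.discretize import discretize_array


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_droi_factory(rng):
    """Random small discretized ROIs (integer levels via exact bin edges)."""

    def make(shape=(5, 5, 5), n_raw_levels=5):
        vals = rng.integers(0, n_raw_levels, shape).astype(float) * 25.0
        mask = np.ones(shape, dtype=bool)
        return discretize_array(vals, mask, 25.0)

    return make
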