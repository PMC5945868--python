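import numpy as np
import pytest

import gwcparc as g


@pytest.fixture(scope="session")
def small_phantom():
    """A 12x12x8 box phantom with 4 planted parcels, shared across tests."""
    spec = g.PhantomSpec(shape=(12, 12, 8), K_true=4, T=40, snr=8.0, seed=1)
    return g.make_phantom(spec)


@pytest.fixture(scope="session")
def small_supervoxels(small_phantom):
    vol, mask, _ = small_phantom
    return g.run_slic(vol, mask, g.SlicParams(n_supervoxels=40, m=10.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
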