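import numpy as np
import pytest

import wavegate as wg


@pytest.fixture(scope="session")
def ilap3_2d_64():
    """The workhorse unitary kernel on a 64 x 64 lattice."""
    return wg.conv_exp(wg.preset_generator("ilap3", 2), (64, 64))


@pytest.fixture(scope="session")
def ilap3_1d_256():
    return wg.conv_exp(wg.preset_generator("ilap3", 1), (256,))


@pytest.fixture(scope="session")
def random7_2d_32():
    return wg.conv_exp(wg.preset_generator("random7", 2, seed=1), (32, 32))


def random_field(shape, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    return scale * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
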