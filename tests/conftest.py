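import numpy as np
import pytest

from spindlemp.dictionary import build_dictionary

FS = 256.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def small_dictionary():
    """Reduced dictionary on a 2-s epoch, cheap enough for brute-force scans."""
    return build_dictionary(
        0.1, FS, 2.0, scale_range=(0.05, 0.45), freq_range=(0.0, 30.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
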