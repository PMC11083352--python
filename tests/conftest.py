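import numpy as np
import pytest

from ccfd.synthetic import SynthParams, generate_lesion_geometry, generate_scan


@pytest.fixture(scope="session")
def small_params():
    """Fast 128-px scan (46.9 µm/px over 6 mm) used by most unit tests."""
    return SynthParams(image_size_px=128, seed=3)


@pytest.fixture(scope="session")
def small_scan(small_params):
    return generate_scan(small_params)


@pytest.fixture(scope="session")
def small_roi(small_params):
    return generate_lesion_geometry(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
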