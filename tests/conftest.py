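import numpy as np
import pytest

from stimlock import GeneratorConfig, build_protocol, simulate_fov
from stimlock.zscoring import zscore_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def protocol():
    """Standard 20 x (1 s on / 3 s off) whisker train."""
    return build_protocol(n_epochs=20, duration_s=1.0, isi_s=3.0)


@pytest.fixture(scope="session")
def small_fov(protocol):
    """32-cell synthetic FOV at generator defaults, with ground truth."""
    traces, truths = simulate_fov(32, protocol, GeneratorConfig(), seed=11)
    return traces, truths


@pytest.fixture(scope="session")
def small_fov_z(small_fov):
    traces, truths = small_fov
    return zscore_matrix(traces), truths
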