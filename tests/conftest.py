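import numpy as np
import pytest

from binoc.synth import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A 300 s session with 4 ROIs per class, shared across encoding tests."""
    return simulate_session(SessionConfig(duration_s=300.0, rng_seed=2, n_rois_per_class=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
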