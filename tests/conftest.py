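import numpy as np
import pytest

from glucowear.fusion import prepare_bundle
from glucowear.simulate import SimConfig, simulate_participant


@pytest.fixture(scope="session")
def one_day_bundle():
    """One synthetic participant-day under the default study conditions."""
    return simulate_participant(SimConfig(n_days=1, seed=123))


@pytest.fixture(scope="session")
def prepared(one_day_bundle):
    """The same participant-day pushed through ingestion + fusion."""
    return prepare_bundle(one_day_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
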