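import numpy as np
import pytest

import nephrops_growth as ng
from nephrops_growth.vbgf_estimation import increments_from_records


@pytest.fixture
def config():
    return ng.SimConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def simulated_increments():
    """Moderate-size simulated tag-recapture set with derived increment columns."""
    records = ng.simulate_tag_recapture(ng.SimConfig(seed=3), 1000)
    return increments_from_records(records)
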