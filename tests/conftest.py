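import numpy as np
import pytest

import bpequant as bq


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default four-class phantom with zero noise and stored truth."""
    return bq.generate_phantom(bq.PhantomSpec(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized three-group cohort from the default (confounded) spec."""
    return bq.generate_cohort(bq.default_cohort_spec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
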