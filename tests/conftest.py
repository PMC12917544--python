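import numpy as np
import pytest

from nirsvar.protocols import make_protocol
from nirsvar.synthetic import default_config, simulate_participant


@pytest.fixture(scope="session")
def nback():
    return make_protocol("nback")


@pytest.fixture(scope="session")
def flanker():
    return make_protocol("flanker")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def synth_config():
    return default_config(seed=42, n_per_group=2)


@pytest.fixture(scope="session")
def pcs_participant(synth_config):
    """One simulated PCS participant, shared across tests (expensive)."""
    return simulate_participant(synth_config, "PCS", "pcs-01", "nback")
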