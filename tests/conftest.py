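import numpy as np
import pytest
from hypothesis import settings

import splicekin as sk

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def network_I():
    return sk.build_pathway(sk.PathwayVariant.from_name("I"))


@pytest.fixture(scope="session")
def traj_I(network_I):
    """One audited wild-type trajectory over the full 900 s window."""
    return sk.simulate(network_I, np.arange(0.0, 901.0, 30.0), seed=7,
                       debug=True)


@pytest.fixture(scope="session")
def ensemble_I(network_I):
    """500-run wild-type ensemble on a 30 s grid."""
    return sk.ensemble_mean(network_I, np.arange(0.0, 901.0, 30.0),
                            n_runs=500, base_seed=101)
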