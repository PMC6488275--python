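import numpy as np
import pytest

from pdiv.simulator import default_config, run_simulation_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pdiv_runs():
    """Record arrays of the default probabilistic-rule simulation, keyed by
    seed; shared across tests to keep the suite fast."""
    cache = {}

    def get(seed: int):
        if seed not in cache:
            cache[seed] = run_simulation_arrays(default_config("pdiv", seed=seed))
        return cache[seed]

    return get
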