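import logging

import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # hypothesis is optional for the suite
    pass

logging.getLogger("cpgsim").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def leaky_problem():
    from cpgsim import make_fixture

    return make_fixture("leaky")


@pytest.fixture(scope="session")
def triad_traces():
    """One adaptive run of the plasticity triad, shared across tests."""
    from cpgsim import make_fixture, run_simulation

    prob = make_fixture("plastic_triad")
    traces, report = run_simulation(prob.spec)
    return prob, traces, report
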