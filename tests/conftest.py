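import numpy as np
import pytest

from processgan.event_log_io import Event, ProcessCase, build_event_log
from processgan.fixture_simulator import clinic_small, simulate_log


@pytest.fixture(scope="session")
def clinic_log():
    """Default fixture log: 250 cases, ~10 activity types, max length 11."""
    return simulate_log(clinic_small(n_cases=250, seed=1))


@pytest.fixture(scope="session")
def small_clinic_log():
    return simulate_log(clinic_small(n_cases=60, seed=2))


@pytest.fixture
def toy_log():
    """Two hand-built cases: {A@0, B@10} and {A@0, C@5, B@20}."""
    cases = [
        ProcessCase("c1", [Event("A", 0.0), Event("B", 10.0)]),
        ProcessCase("c2", [Event("A", 0.0), Event("C", 5.0), Event("B", 20.0)]),
    ]
    return build_event_log(cases)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
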