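import numpy as np
import pytest

from n2osink.bethedge import BetHedgeParams, simulate
from n2osink.incubation import VialSpec

INIT_HEADSPACE = {"O2": 9e-5, "N2O": 1e-4, "N2": 0.0}


@pytest.fixture(scope="session")
def default_vial() -> VialSpec:
    return VialSpec()


@pytest.fixture(scope="session")
def default_params() -> BetHedgeParams:
    return BetHedgeParams()


@pytest.fixture(scope="session")
def init_headspace() -> dict:
    return dict(INIT_HEADSPACE)


@pytest.fixture(scope="session")
def reference_sim(default_params, default_vial, init_headspace):
    """One hourly-sampled vial simulation shared across tests."""
    schedule = np.arange(1.0, 60.0, 1.0)
    t_eval = np.union1d(np.linspace(0.0, 60.0, 401), schedule)
    return simulate(default_params, default_vial, init_headspace,
                    sampling_times_h=schedule, t_end_h=60.0, t_eval=t_eval)
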