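import numpy as np
import pytest

from dptpbpk import (
    DoseEvent,
    PbpkModel,
    SimulationSettings,
    load_builtin_profile,
)
from dptpbpk.io import OBSERVED_SCHEDULES


@pytest.fixture(scope="session")
def profiles():
    return {name: load_builtin_profile(name) for name in
            ("mouse", "rat", "monkey", "dog", "human")}


@pytest.fixture(scope="session")
def human(profiles):
    return profiles["human"]


@pytest.fixture(scope="session")
def rat(profiles):
    return profiles["rat"]


@pytest.fixture(scope="session")
def mouse(profiles):
    return profiles["mouse"]


@pytest.fixture(scope="session")
def human_16mg_result(human):
    """Typical human simulation: 16 mg i.v., observed-schedule output."""
    schedule = np.asarray(OBSERVED_SCHEDULES["human"], dtype=float)
    settings = SimulationSettings(t_end=float(schedule[-1]), grid=schedule)
    return PbpkModel(human).simulate(DoseEvent(16000.0), settings)
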