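import numpy as np
import pytest

from cardioprofile.engine import PacingProtocol, StepController, pace
from cardioprofile.synthetic_fixtures import (
    TOY_MODEL,
    SyntheticAPSpec,
    make_toy_cell,
    synth_ap_trace,
)


@pytest.fixture(scope="session")
def toy_cell():
    return make_toy_cell("normal")


@pytest.fixture(scope="session")
def toy_paced():
    """Toy cell paced to steady state at CL = 1000 ms (shared, read-only)."""
    params, state = make_toy_cell("normal")
    proto = PacingProtocol(cl=1000.0, max_beats=50, ss_window=6)
    return pace(TOY_MODEL, params, proto, StepController(), keep_beats=6)


@pytest.fixture
def clean_trace():
    spec = SyntheticAPSpec(seed=1)
    return synth_ap_trace(spec)


@pytest.fixture
def ead_trace():
    # humps at 250 and 400 ms sit on the upper descent (above the -40 mV
    # EAD gate) when the descent lasts 700 ms
    spec = SyntheticAPSpec(apd=700.0,
                           ead_events=[(250.0, 8.0, 40.0), (400.0, 8.0, 40.0)],
                           seed=2)
    return synth_ap_trace(spec)
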