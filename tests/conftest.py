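import numpy as np
import pytest

from scdeconv.design import Trial, TrialDesign
from scdeconv.model_core import TimeGrid, canonical_rf


@pytest.fixture(scope="session")
def rf_scr():
    return canonical_rf("scr")


@pytest.fixture(scope="session")
def rf_sf():
    return canonical_rf("sf")


@pytest.fixture
def grid10():
    """100 s at 10 Hz."""
    return TimeGrid(sampling_rate=10.0, n_samples=1000)


@pytest.fixture
def small_design():
    """Four trials, SOA 3.5 s, ITIs ~9 s, 2 reinforced CS+."""
    trials = [
        Trial(index=0, cs_onset=10.0, soa=3.5, cs_type="CS+", reinforced=True),
        Trial(index=1, cs_onset=22.5, soa=3.5, cs_type="CS-"),
        Trial(index=2, cs_onset=35.0, soa=3.5, cs_type="CS+", reinforced=False),
        Trial(index=3, cs_onset=47.5, soa=3.5, cs_type="CS+", reinforced=True),
    ]
    return TrialDesign(trials=trials, session_end=70.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
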