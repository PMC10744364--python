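import numpy as np
import pytest

from specratio.cohort import SyntheticCohortSpec, generate_cohort
from specratio.montage import CHANNELS_1020
from specratio.referencing import build_head_model


@pytest.fixture(scope="session")
def head_model():
    """Default 19-channel spherical head model (expensive; shared)."""
    return build_head_model(CHANNELS_1020)


@pytest.fixture(scope="session")
def small_cohort():
    """Small fast cohort with the default group effects (8 FTD / 8 CTL,
    20 s at 500 Hz)."""
    spec = SyntheticCohortSpec(n_ftd=8, n_ctl=8, fs=500.0, duration=20.0, seed=11)
    recordings, subjects = generate_cohort(spec)
    return spec, recordings, subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
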