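import logging

import numpy as np
import pytest

from ventfc import generate_montage, simulate_recording
from ventfc.synthetic import RecordingParams

logging.getLogger("ventfc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def montage20():
    return generate_montage()


@pytest.fixture(scope="session")
def montage_small():
    """6 channels, 3 per hemisphere: cheap stand-in for statistical studies."""
    return generate_montage(3)


@pytest.fixture(scope="session")
def clean_recording(montage20):
    """Artifact-free 408-s session with every channel carrying cardiac."""
    params = RecordingParams(motion_rate_per_min=0.0, dropout_rate_per_min=0.0,
                             cardiac_free_rate=0.0)
    rec, truth = simulate_recording(montage20, 408.0, 10.17, params, seed=101)
    return rec, truth


@pytest.fixture(scope="session")
def default_recording(montage20):
    """Default-condition session (motion, dropout, cardiac-free channels)."""
    rec, truth = simulate_recording(montage20, 408.0, 10.17, seed=7)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
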