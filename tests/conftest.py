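import numpy as np
import pytest

from gaitmode import SimConfig, generate_trial
from gaitmode.pipeline import PipelineConfig, prepare_trial


@pytest.fixture(scope="session")
def default_trial():
    """One Set-A trial at the default noise level."""
    return generate_trial(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free deterministic template trial."""
    return generate_trial(SimConfig(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def prepared_trial(default_trial):
    rec, gt = default_trial
    return prepare_trial(rec, gt, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
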