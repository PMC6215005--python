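import numpy as np
import pytest

from nogodecode.montage import default_channels
from nogodecode.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small but structurally complete cohort: 16 channels (CSD minimum),
    64 Hz, 8 subjects, 60 trials."""
    return SimConfig(n_subjects=8, channels=default_channels(16), fs=64.0,
                     epoch_window_ms=(-1000.0, 1500.0), n_trials=60,
                     effect_size=1.0, seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    cohort, behavior, manifest = generate_cohort(tiny_config)
    return cohort, behavior, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
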