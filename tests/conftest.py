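import numpy as np
import pytest

from oscdecode import SimConfig, generate_trials


@pytest.fixture(scope="session")
def small_epochs():
    """A small quiet cohort member used by several structural tests."""
    cfg = SimConfig(n_trials=24, n_channels=4, noise_sd=0.3, seed=11)
    epochs, gt = generate_trials(cfg)
    return epochs, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
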