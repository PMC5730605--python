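import numpy as np
import pytest

from errpbandit.synthdata import gen_epoch_set, gen_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_epoch_set():
    """Two 45-trial observation sets at 16 channels — enough structure for
    pipeline unit tests without the full 64-channel cost."""
    rng = np.random.default_rng(99)
    epochs = []
    for _ in range(2):
        schedule = gen_schedule("training", n_trials=45, n_err=9, rng=rng)
        epochs.extend(gen_epoch_set(schedule, snr=0.8, n_channels=16, rng=rng))
    return epochs
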