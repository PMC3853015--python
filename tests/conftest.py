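import dataclasses

import numpy as np
import pytest

from micsp.io_preprocess import Epochs, common_average_reference, prepare_for_csp
from micsp.synth import SynthConfig, generate

#: 16-channel sensorimotor montage subset used by the fast end-to-end tests
SMALL_CHANNELS = (
    "FC3", "FCZ", "FC4",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP3", "CPZ", "CP4",
    "P3", "PZ", "P4",
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_epochs(rng):
    """Small random 4-channel epochs, 3 classes, 6 trials each."""
    data = rng.standard_normal((18, 4, 256))
    labels = np.repeat([1, 2, 3], 6)
    return Epochs(data=data, labels=labels, fs=128.0, channels=["A", "B", "C", "D"])


@pytest.fixture(scope="session")
def small_synth():
    """Deterministic small synthetic session (16 ch, 10 trials/class, 200 Hz)."""
    cfg = dataclasses.replace(
        SynthConfig(), channels=SMALL_CHANNELS, fs=200.0, n_trials_per_class=10,
        noise_level=0.3, seed=77,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_synth_csp(small_synth):
    """The small session preprocessed for CSP (CAR, 8-30 Hz, 3.5-6.5 s)."""
    epochs, gt = small_synth
    return prepare_for_csp(common_average_reference(epochs)), gt
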