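import numpy as np
import pytest

from cmephys.beats import detect_ap_beats
from cmephys.synth import gen_ap_train


@pytest.fixture(scope="session")
def clean_ap_train():
    """Noise-free 60 BPM / 60 s AP train with its ground truth."""
    return gen_ap_train(60.0, 60.0, noise_sd_mv=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_ap_beats(clean_ap_train):
    trace, _ = clean_ap_train
    return detect_ap_beats(trace)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
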