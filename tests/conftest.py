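import numpy as np
import pytest

from beatfusion import preprocess, synth


@pytest.fixture(scope="session")
def default_record():
    """One default-condition synthetic record (360 Hz, 5 classes, all noises on)."""
    return synth.generate_record(synth.SynthConfig(seed=0, n_beats=60))


@pytest.fixture(scope="session")
def denoised_record(default_record):
    sig = preprocess.denoise(default_record.samples, default_record.sampling_rate)
    return default_record, sig


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
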