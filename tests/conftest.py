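import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six-class synthetic dataset, 5 segments per class, 4 s at 250 Hz."""
    from eegart.synth import generate_dataset

    classes = ["CHEW", "MUSC", "ELEC", "EYEM", "RC", "BLINK"]
    return generate_dataset({c: 5 for c in classes}, duration_s=4.0, fs=250.0,
                            snr_db=10.0, seed=7)
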