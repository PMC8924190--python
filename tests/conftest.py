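import numpy as np
import pytest

from evoseizure.features import WINDOW_SAMPLES
from evoseizure.io import Recording
from evoseizure.synth import SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def noise_window(rng):
    """One 5-s window of standard-normal noise."""
    return rng.standard_normal(WINDOW_SAMPLES)


@pytest.fixture(scope="session")
def white_recording():
    """Tiny seizure-free white-noise recording (2 channels, 60 s, 256 Hz)."""
    r = np.random.default_rng(42)
    return Recording(
        channels=["C3", "C4"],
        fs=256.0,
        samples=(20.0 * r.standard_normal((2, 256 * 60))).astype(np.float32),
    )


@pytest.fixture(scope="session")
def planted_recording():
    """Small planted synthetic patient: 4 channels, 3 seizures, step drift
    of the variance feature on C3 (generator defaults otherwise).

    Session-scoped: generation covers ~12 h of signal.
    """
    cfg = SynthConfig(
        n_channels=4,
        channels=("C3", "C4", "F3", "P3"),
        n_seizures=3,
        seed=7,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def planted_tensor(planted_recording):
    from evoseizure.features import build_feature_tensor

    return build_feature_tensor(planted_recording)
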