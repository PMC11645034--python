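import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from eegemo import synth  # noqa: E402
from eegemo.types import RawEEG  # noqa: E402


@pytest.fixture(scope="session")
def fs() -> float:
    return 128.0


@pytest.fixture(scope="session")
def sine_eeg(fs):
    """Two channels of pure 10 Hz alpha, 30 s."""
    t = np.arange(0, 30, 1 / fs)
    x = 10 * np.sin(2 * np.pi * 10 * t)
    return RawEEG(data=np.stack([x, x]), fs=fs)


@pytest.fixture(scope="session")
def small_dataset():
    """16-channel four-class set, strong effect, small enough for fast tests."""
    cfg = synth.SynthConfig(n_channels=16, fs=128.0, duration=12.0, seed=11)
    return synth.gen_labeled_dataset(8, 3.0, "four-class", cfg)


@pytest.fixture(scope="session")
def vad_dataset():
    cfg = synth.SynthConfig(n_channels=16, fs=128.0, duration=10.0, seed=13)
    return synth.gen_labeled_dataset(6, 3.0, "vad-binary", cfg)
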