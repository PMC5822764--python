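import numpy as np
import pytest

from icgflow.io import FrameStack
from icgflow.kinetics import KineticsConfig
from icgflow.simulate import default_profiles


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def hand_profiles():
    return default_profiles("hand")


@pytest.fixture(scope="session")
def protocol_times():
    """Frame times of the acquisition protocol: 120 frames at 5 s."""
    return np.arange(120) * 5.0


@pytest.fixture
def no_floor_config():
    """Extraction config with the noise-floor validity check disabled,
    for noiseless synthetic curves whose pre-onset samples have zero SD."""
    return KineticsConfig(noise_floor_sd=0.0)


def constant_stack(value, n_frames=6, shape=(8, 10), dt=5.0, pixel_size_mm=0.5):
    frames = np.full((n_frames,) + shape, float(value))
    return FrameStack(frames, np.arange(n_frames) * dt, pixel_size_mm)


@pytest.fixture
def make_constant_stack():
    return constant_stack
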