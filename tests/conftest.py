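import numpy as np
import pytest

from fatiguebrake import EEGRecording, FatigueProfile, generate_eeg


@pytest.fixture(scope="session")
def study_frame_fixture():
    from fatiguebrake import study_frame

    return study_frame()


@pytest.fixture
def sine_recording():
    """Pure 10 Hz tone on two channels, 8 s at 128 Hz."""
    fs = 128.0
    t = np.arange(int(8 * fs)) / fs
    x = np.sin(2 * np.pi * 10.0 * t)
    return EEGRecording(data=np.vstack([x, 0.5 * x]), fs=fs)


@pytest.fixture
def short_eeg():
    """Default-profile synthetic recording, 8 s, 4 channels."""
    return generate_eeg(FatigueProfile(), n_channels=4, fs=128.0, duration=8.0, seed=7)
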