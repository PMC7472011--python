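import numpy as np
import pytest

from stresswin import Montage, Recording, SynthSpec, generate_recording


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage()


@pytest.fixture(scope="session")
def short_recording() -> Recording:
    """Two-second default-spec synthetic recording (fast, deterministic)."""
    return generate_recording(SynthSpec(n_subjects=1, session_length=1.0, seed=42), 0)


@pytest.fixture()
def sine_recording(montage) -> Recording:
    """10 s of a pure 10 Hz, 50 uV sinusoid on every channel at 500 Hz."""
    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    wave = 50.0 * np.sin(2 * np.pi * 10.0 * t)
    data = np.tile(wave, (19, 1))
    return Recording(subject_id="sine", data=data, sampling_rate=fs, montage=montage)


def make_recording(data: np.ndarray, fs: float = 500.0, subject_id: str = "t", **kw) -> Recording:
    return Recording(subject_id=subject_id, data=data, sampling_rate=fs, **kw)
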