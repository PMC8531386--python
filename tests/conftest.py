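import numpy as np
import pytest

from graphrely import BandDefinition, Recording, StudyDesign


@pytest.fixture
def alpha_band() -> BandDefinition:
    return BandDefinition("alpha1", 8.0, 10.5)


@pytest.fixture
def tiny_design() -> StudyDesign:
    """Desk-scale two-channel design for estimator tests."""
    return StudyDesign(n_participants=2, duration=40.0, n_channels=2,
                       sampling_rate=256.0)


def make_noise_recording(n_channels: int, duration: float, seed: int,
                         fs: float = 256.0) -> Recording:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_channels, int(duration * fs)))
    labels = [f"Ch{c + 1:02d}" for c in range(n_channels)]
    return Recording(x, fs, labels)
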