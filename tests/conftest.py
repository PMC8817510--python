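import numpy as np
import pytest

from icpshape.core import Recording
from icpshape.synthetic import PatternSpec, SyntheticSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_three_segment():
    """Noiseless recording of three known segments (no spikes, no
    oscillations) with its ground truth."""
    spec = SyntheticSpec(
        duration_s=900.0,
        fs=100.0,
        pattern_menu=[
            PatternSpec("sinusoid", (4.0, 4.0), (300.0, 300.0)),
            PatternSpec("ramp_asym", (5.0, 5.0), (300.0, 300.0)),
        ],
        cardiac_amp_mmHg=0.0,
        resp_amp_mmHg=0.0,
        noise_sd_mmHg=0.0,
        n_spikes=0,
        seed=7,
    )
    return generate_recording(spec)


@pytest.fixture(scope="session")
def noisy_recording():
    """Default-condition synthetic recording (10 min) with spikes."""
    spec = SyntheticSpec(duration_s=600.0, n_spikes=2, seed=11)
    return generate_recording(spec)


@pytest.fixture
def short_recording():
    """Small, fast Recording for I/O-level tests."""
    t = np.arange(2000) / 100.0
    return Recording(samples=10.0 + np.sin(2 * np.pi * 0.5 * t), fs=100.0, id="short")
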