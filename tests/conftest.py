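import numpy as np
import pytest

from breathseg.audio_io import AudioSignal
from breathseg.phase_segmentation import build_reference_hmm
from breathseg.synthetic import BreathSpec, HeartSpec, NoiseSpec, mix_recording

RATE = 16000


def make_sine(freq_hz: float, duration_s: float, rate: int = RATE, amp: float = 1.0) -> AudioSignal:
    t = np.arange(int(round(duration_s * rate))) / rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq_hz * t), rate)


@pytest.fixture(scope="session")
def sine_200hz() -> AudioSignal:
    return make_sine(200.0, 1.0)


@pytest.fixture(scope="session")
def white_noise() -> AudioSignal:
    rng = np.random.default_rng(1234)
    return AudioSignal(0.5 * rng.standard_normal(RATE), RATE)


@pytest.fixture(scope="session")
def reference_model():
    """The default six-state phase model (built once; deterministic)."""
    return build_reference_hmm()


@pytest.fixture(scope="session")
def default_mixture():
    """One default synthetic recording with truth labels."""
    return mix_recording(
        BreathSpec(seed=11), HeartSpec(seed=12), NoiseSpec(), seed=13
    )
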