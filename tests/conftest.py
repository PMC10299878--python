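import numpy as np
import pytest

from swaylab import COPTrial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_circle_trial(radius=1.0, freq=0.5, fs=100.0, duration=30.0):
    """COP moving uniformly on a circle: radius and speed known in closed form."""
    t = np.arange(int(round(duration * fs))) / fs
    return COPTrial(
        ap=radius * np.cos(2 * np.pi * freq * t),
        ml=radius * np.sin(2 * np.pi * freq * t),
        fs=fs,
    )


def make_tone_trial(freq=0.4, amp=1.0, fs=100.0, duration=30.0, phase=0.0):
    """Single sinusoid on the AP channel, ML mirrored in quadrature."""
    t = np.arange(int(round(duration * fs))) / fs
    return COPTrial(
        ap=amp * np.sin(2 * np.pi * freq * t + phase),
        ml=amp * np.cos(2 * np.pi * freq * t + phase),
        fs=fs,
    )


@pytest.fixture
def circle_trial():
    return make_circle_trial()


@pytest.fixture
def tone_trial():
    return make_tone_trial()


@pytest.fixture
def noise_trial(rng):
    return COPTrial(
        ap=rng.normal(0, 2.0, 3000), ml=rng.normal(0, 2.0, 3000), fs=100.0
    )
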