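import numpy as np
import pytest

from plvnet.bands import ALPHA
from plvnet.montage import Montage, default_montage
from plvnet.recording import Annotation, EpochSet, Recording


@pytest.fixture(scope="session")
def montage62():
    return default_montage()


@pytest.fixture()
def montage8():
    """Small montage with atlas-classifiable 10-20 names."""
    names = ["F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]
    rng = np.random.default_rng(0)
    return Montage(names, rng.normal(size=(8, 3)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sine_recording(freq_hz: float, fs: float = 600.0, duration_s: float = 10.0,
                   n_channels: int = 2, amplitude: float = 1.0) -> Recording:
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (n_channels, 1))
    return Recording(
        data=data, fs=fs, channels=[f"ch{i}" for i in range(n_channels)],
        annotations=[Annotation("RS", 0.0, duration_s)],
    )


@pytest.fixture()
def alpha_band():
    return ALPHA


def make_epochs(data: np.ndarray, fs: float = 600.0, stage: str = "RS",
                band=None) -> EpochSet:
    return EpochSet(
        epochs=data, fs=fs, channels=[f"ch{i}" for i in range(data.shape[1])],
        stage=stage, band=band,
    )
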