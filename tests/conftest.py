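import numpy as np
import pytest

from eegnetkit.montage import MONTAGE_16
from eegnetkit.preprocess import BandSignals
from eegnetkit.recording import EEGRecording
from eegnetkit.synthetic import CouplingSpec, generate_band_sources


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """16 identical 6 Hz tones at 128 Hz, 30 s."""
    t = np.arange(int(30 * 128)) / 128
    tone = 50.0 * np.sin(2 * np.pi * 6 * t)
    return EEGRecording(data=np.tile(tone, (16, 1)), rate=128.0)


@pytest.fixture
def noise_recording(rng):
    """16-channel white-noise recording at 128 Hz, 20 s."""
    return EEGRecording(data=rng.standard_normal((16, 20 * 128)), rate=128.0)


@pytest.fixture
def coupled_band_signals(rng):
    """Alpha band signals with moderate global coupling, 60 s at 128 Hz."""
    spec = CouplingSpec(band="alpha", global_coupling=0.5,
                        within_community_coupling=0.2, noise_sd=0.0)
    data = generate_band_sources(spec, 60.0, 128.0, rng)
    return BandSignals(band="alpha", data=data, rate=128.0, channel_labels=MONTAGE_16)


def random_connectivity(rng, n=6, order="low", band="delta"):
    """Random valid symmetric connectivity matrix on the first n montage channels."""
    from eegnetkit.connectivity import ConnectivityMatrix

    w = rng.uniform(0.05, 0.95, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        weights=w, order=order, band=band, channel_labels=MONTAGE_16[:n]
    )
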