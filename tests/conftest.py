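import numpy as np
import pytest

from formantcomp.contours import FormantTrack
from formantcomp.synthdata import SyntheticSentenceSpec, make_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(20140519)


@pytest.fixture
def random_track(rng):
    """A smooth random formant-like track, ~1 s at 1-ms frames."""
    n = 1000
    t = np.arange(n) * 0.001
    dev = 0.3 * np.cos(2 * np.pi * 3.1 * t + 0.7) + 0.1 * np.cos(2 * np.pi * 5.3 * t)
    return FormantTrack(
        freqs=1500.0 * np.exp(dev),
        amps=0.5 + 0.5 * np.abs(np.sin(2 * np.pi * 4 * t)),
        label="F2",
    )


@pytest.fixture
def sentence():
    """One deterministic synthetic sentence (2 s)."""
    return make_tracks(SyntheticSentenceSpec(duration=2.0, rng_seed=42), "s001")


def random_tracks(seed, count, n_frames=200):
    """Stream of random positive-frequency tracks for property sweeps."""
    gen = np.random.default_rng(seed)
    for _ in range(count):
        freqs = np.exp(gen.uniform(np.log(200), np.log(3000), size=n_frames))
        amps = gen.uniform(0, 1, size=n_frames)
        yield FormantTrack(freqs=freqs, amps=amps)
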