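import numpy as np
import pytest

from ciliabeat import BeatModel, simulate_kymograph

#: Nuisance profile that turns every stochastic model component off.
NOISELESS = dict(noise_sd=0.0, freq_jitter_sd=0.0, drift_sd=0.0,
                 background_sd=0.0, freq_spread_rel=0.0,
                 amplitude_spread_rel=0.0)


def pure_tone_model(freq, seed=0, **overrides):
    """A noiseless, synchronous, single-harmonic (pure cosine) beat model."""
    params = dict(NOISELESS, harmonics=(), metachronal_wavelength=np.inf)
    params.update(overrides)
    return BeatModel(true_cbf=freq, seed=seed, **params)


@pytest.fixture
def tone_kymograph():
    """Noiseless 10 Hz cosine kymograph, 1 s @ 300 fps, 20 positions."""
    return simulate_kymograph(pure_tone_model(10.0), 300, 1.0, 20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
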