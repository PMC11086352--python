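import numpy as np
import pytest

from emgsynergy import (
    EMGEnvelope, make_synergy_bank, simulate_activations, synthesize_envelope,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bank():
    """A 14-channel, 3-synergy bank with planted negative weights."""
    return make_synergy_bank(14, 3, 0.2, seed=11)


@pytest.fixture
def clean_envelope(small_bank):
    """Noiseless envelope generated from the small bank."""
    C = simulate_activations(600, 3, smoothness_ms=100, fs=100, seed=21,
                             shift=0.3)
    return synthesize_envelope(small_bank, C, noise_sd=0.0, seed=31), C


@pytest.fixture
def flat_envelope():
    """A featureless nonnegative envelope for degenerate-geometry checks."""
    rng = np.random.default_rng(7)
    data = 1.0 + 0.01 * rng.random((4, 200))
    return EMGEnvelope(data, 100.0, [f"ch{i}" for i in range(4)])
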