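import numpy as np
import pytest

from pvcdetect.synthetic_ecg import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_mixed_record():
    """Noise-free record with a mix of normal and PVC beats."""
    return generate_record(
        SynthConfig(n_beats=60, pvc_fraction=0.3, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_mixed_record():
    """200-beat record with additive noise, as a detector workout."""
    return generate_record(
        SynthConfig(n_beats=200, pvc_fraction=0.3, noise_sd=0.02, seed=2))


@pytest.fixture(scope="session")
def all_normal_record():
    return generate_record(
        SynthConfig(n_beats=100, pvc_fraction=0.0, noise_sd=0.0, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
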