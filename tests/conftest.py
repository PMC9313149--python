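import numpy as np
import pytest

from hctnet.synth import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def small_synth():
    """200-image, 4-class, 64x64 synthetic dataset shared across tests."""
    return generate_dataset(
        SynthSpec(n_patients=10, scans_per_patient=5, image_size=64, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
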