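import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 seeded 32x32 synthetic lesion samples shared across tests."""
    from ghdcnet.data import SynthConfig, generate_synthetic

    cfg = SynthConfig(image_size=(32, 32), blob_radius=(4.0, 9.0), blob_count=(1, 1), seed=3)
    return generate_synthetic(cfg, 12)
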