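import numpy as np
import pytest

from msnet import preprocess, synthdata


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """A small normalized 64x64 two-class phantom dataset (30 MS / 30 HC)."""
    params = synthdata.SynthParams(image_side=64, plaque_contrast=0.35, seed=7)
    dataset, _ = synthdata.generate_dataset(params, 30, 30, seed=7)
    return preprocess.normalize_dataset(dataset)


@pytest.fixture(scope="session")
def gradient_image():
    """A deterministic non-constant 32x32 test image in [0, 1]."""
    g = np.linspace(0.0, 1.0, 32)
    return np.outer(g, g[::-1])
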