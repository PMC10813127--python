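import numpy as np
import pytest

from dspkd.synthdata import ClassSignature, SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_two_class():
    """Small, well-separated 2-class dataset: 32 images per class at 32x32."""
    spec = SynthSpec(
        n_classes=2, images_per_class=32, side=32, seed=7,
        signatures=[ClassSignature(hue=0.05, radius_frac=0.2, eccentricity=1.0, texture_freq=0.0),
                    ClassSignature(hue=0.45, radius_frac=0.3, eccentricity=0.6, texture_freq=3.0)],
        hue_jitter=0.02, noise_sd=0.03)
    ds = generate_dataset(spec)
    return ds.images, ds.labels


@pytest.fixture(scope="session")
def hairy_pairs():
    """Clean/corrupted image pairs with ground-truth hair masks."""
    spec = SynthSpec(n_classes=2, images_per_class=6, side=64, seed=11,
                     hair_probability=1.0)
    ds = generate_dataset(spec)
    return ds
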