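import dataclasses

import numpy as np
import pytest

from swarmseg.phantoms import PhantomSpec, derive_seed, generate_phantom


@pytest.fixture
def two_level_spec():
    """Noiseless, unlit, hairless single-blob phantom: exactly two levels."""
    return PhantomSpec(
        width=64,
        height=64,
        n_blobs=1,
        blob_intensity_mean=200.0,
        background_intensity_mean=40.0,
        noise_sigma=0.0,
        illumination_gradient=0.0,
        hair_count=0,
        seed=7,
    )


@pytest.fixture
def two_level_phantom(two_level_spec):
    return generate_phantom(two_level_spec)


@pytest.fixture
def noisy_spec():
    return PhantomSpec(width=64, height=64, noise_sigma=20.0,
                       illumination_gradient=0.2, seed=0)


def make_noisy_phantoms(spec, n, master_seed):
    return [
        generate_phantom(dataclasses.replace(spec, seed=derive_seed(master_seed, i)))
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
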