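import numpy as np
import pytest

from mgrnnm import SyntheticSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synthetic():
    """A 60x30 rank-3 graph-consistent dataset with noiseless labels."""
    return generate_synthetic(
        SyntheticSpec(
            n_drugs=60, n_targets=30, latent_rank=3,
            interaction_density=0.15, label_flip_rate=0.0, seed=1,
        )
    )


def random_binary(rng, n, m, density=0.3):
    return (rng.random((n, m)) < density).astype(float)
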