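import numpy as np
import pytest

from mammodensity.phantoms import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_phantoms():
    """A dozen 64x64 phantoms with mixed views, shared across tests."""
    base = PhantomSpec(height=64, width=64)
    samples, manifest = generate_dataset(
        12, {"pd_range": (5.0, 45.0), "view_mix": 0.5}, seed=42, base_spec=base)
    return samples, manifest


def random_mask_pair(rng, shape=(8, 8)):
    """Independent random binary masks for oracle comparisons."""
    return (
        (rng.random(shape) > rng.uniform(0.2, 0.8)).astype(np.uint8),
        (rng.random(shape) > rng.uniform(0.2, 0.8)).astype(np.uint8),
    )
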