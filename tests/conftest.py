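import numpy as np
import pytest

from irtexture import CohortSpec, GrayImage, RegionMask, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Fast strong-effect cohort for integration-style tests."""
    return CohortSpec(
        n_cases=6,
        n_controls=6,
        height=128,
        width=128,
        corr_length_control=8.0,
        corr_length_case=2.0,
        lesion_count=15,
        disc_radius=16,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.integers(0, 256, size=(16, 16)), bit_depth=8)


def random_quantized(rng, shape=(12, 12), ng=6, mask_frac=0.2):
    """Random levels 1..ng with a random exclusion mask (0 sentinel)."""
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) >= mask_frac
    levels[~mask] = 0
    return levels, RegionMask(mask)
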