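import numpy as np
import pytest

from rtlipred.synthcohort import CohortConfig, POSITIVE, generate_subject


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_positive=2, n_negative=2, volume_shape=(32, 32, 16), seed=7)


@pytest.fixture(scope="session")
def small_subject(small_config):
    """One positive subject on a small grid, shared by read-only tests."""
    return generate_subject(small_config, POSITIVE, np.random.default_rng(42), "subX")


def random_quantized_roi(rng, max_side=8, n_levels=4):
    """Random cuboid ROI with random gray levels, for oracle comparisons."""
    from rtlipred.texture import QuantizedROI

    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    mask = np.ones(shape, dtype=bool)
    if rng.random() < 0.5:  # occasionally knock holes in the mask
        mask &= rng.random(shape) > 0.2
        if not mask.any():
            mask[0, 0, 0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedROI(levels=levels, mask=mask, n_levels=n_levels)
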