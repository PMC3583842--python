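import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vasomet import PixelMask

settings.register_profile(
    "ci", derandomize=True, max_examples=40, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_mask(rng: np.random.Generator, shape=(30, 30), p=0.1, pixel_size_um=1.0) -> PixelMask:
    """A Bernoulli random mask; p is the foreground density."""
    return PixelMask(rng.random(shape) < p, pixel_size_um)


def nonempty_random_mask(rng, shape=(30, 30), p=0.1, pixel_size_um=1.0) -> PixelMask:
    mask = random_mask(rng, shape, p, pixel_size_um)
    if not mask.grid.any():
        grid = mask.grid.copy()
        grid[tuple(rng.integers(0, s) for s in shape)] = True
        mask = PixelMask(grid, pixel_size_um)
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)
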