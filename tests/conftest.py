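"""Shared fixtures: small synthetic landscapes reused across test modules."""

import numpy as np
import pytest

from afbiomass.grids import Grid2D
from afbiomass.synthdata import LandscapeConfig, generate_truth


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """48 x 48 landscape: fast but large enough for window statistics."""
    return LandscapeConfig(nrows=48, ncols=48)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config, seed=11)


@pytest.fixture(scope="session")
def default_truth():
    """Full default-scale truth (128 x 128), shared read-only."""
    return generate_truth(LandscapeConfig(), seed=5)


@pytest.fixture()
def flat_grid():
    def make(value=1.0, shape=(16, 16), pixel=50.0):
        arr = np.full(shape, float(value))
        return Grid2D(arr, np.zeros(shape, bool), pixel_size_m=pixel,
                      origin=(0.0, shape[0] * pixel))
    return make
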