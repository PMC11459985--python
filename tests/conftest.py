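import numpy as np
import pytest

from phantomrad import (RunConfig, default_geometry, default_insert_configs)
from phantomrad.features.discretize import DiscretizedROI


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()

@pytest.fixture(scope="session")
def insert_configs():
    return default_insert_configs()


@pytest.fixture
def small_run_config():
    """Reduced reconstruction grid for fast pipeline contract tests."""
    cfg = RunConfig(seed=7)
    cfg.variations = {
        "subsets": [12, 24],
        "iterations": [1, 2],
        "filter": [0.0, 2.0, 6.0],
        "tof": [True, False],
    }
    return cfg


def droi_from_levels(levels, ng=None):
    """Wrap a sentinel-0 integer grid as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim < 3:
        levels = levels.reshape((1,) * (3 - levels.ndim) + levels.shape)
    mask = levels > 0
    if ng is None:
        ng = max(2, int(levels.max()))
    return DiscretizedROI(levels, int(ng), mask)


@pytest.fixture
def make_droi():
    return droi_from_levels
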