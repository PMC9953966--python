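from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tauradiomics import CohortSpec, LabelMap, Volume, generate_atlas


EYE2 = np.diag([2.0, 2.0, 2.0, 1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.normal(size=(16, 16, 16)), EYE2.copy())


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale cohort spec used by several end-to-end tests."""
    return CohortSpec(n_per_group=10, shape=(40, 40, 40), n_regions=15,
                      n_affected=6, mean_shift=2.0, texture_effect=0.5, seed=7)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_spec) -> LabelMap:
    return generate_atlas(tiny_spec)


def random_quantized(rng, shape=(4, 4, 4), ng=4, p_bg=0.2):
    """Random quantized ROI grid with background holes, for oracle tests."""
    from tauradiomics.texture import QuantizedROI

    grid = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    grid[rng.random(shape) < p_bg] = 0
    if (grid > 0).sum() == 0:
        grid[0, 0, 0] = 1
    levels = grid[grid > 0]
    return QuantizedROI(grid, levels, ng, np.arange(1, ng) + 0.5,
                        np.arange(1, ng + 1, dtype=float))
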