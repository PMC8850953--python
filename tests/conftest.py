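from __future__ import annotations

import numpy as np
import pytest

from netcog import NullModelConfig, SparsityGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return SparsityGrid()


@pytest.fixture
def light_null():
    """Small null ensemble for fast tests."""
    return NullModelConfig(n_randomizations=5, swaps_per_edge=5, seed=0)


@pytest.fixture
def toy_timeseries(rng):
    """30 regions x 80 timepoints of weakly correlated noise."""
    base = rng.standard_normal((30, 80))
    shared = rng.standard_normal(80)
    return base + 0.3 * shared
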