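import numpy as np
import pytest

from phagegrid import SimParams, init_population, new_grid, place_eps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A 20x20 clustered-EPS world, short run, baseline rates."""
    return SimParams(width=20, height=20, burst_b=6, eps_fraction_E=0.3,
                     eps_layout="clustered_rows", k_C=0.25, k_E=0.35,
                     cell_repro_prob=0.1, diffuse_fraction=0.3,
                     n_steps=300, avg_window=100, seed=11)


def build_world(params):
    grid = new_grid(params)
    place_eps(grid, params)
    init_population(grid, params)
    return grid


@pytest.fixture
def small_world(small_params):
    return build_world(small_params)
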