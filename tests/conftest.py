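import numpy as np
import pytest

from fsbdmc import SimConfig, build_grid, hermitize


@pytest.fixture
def small_grid():
    """An L = 240 nm box with lambda_min = 20 nm (N = 24)."""
    return build_grid(240.0, 12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_hermitian_field(grid, rng, scale=1.0):
    """A random conjugate-symmetric spectral field (real height field)."""
    g = rng.standard_normal((grid.N, grid.N)) + 1j * rng.standard_normal(
        (grid.N, grid.N)
    )
    return hermitize(scale * g, grid)


@pytest.fixture
def hermitian_field(small_grid, rng):
    return random_hermitian_field(small_grid, rng, scale=100.0)


@pytest.fixture
def quick_config():
    return SimConfig(L=240.0, alpha_max=12, t_total=1000.0, dt=0.5)
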