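import numpy as np
import pytest

from colonyrot.grid import Grid


@pytest.fixture
def grid32():
    return Grid(32, 32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def smooth_random_field(grid: Grid, rng, amplitude=0.1, modes=3):
    """Band-limited random periodic field (smooth enough for stencils)."""
    x, y = grid.meshgrid()
    f = np.zeros(grid.shape)
    for _ in range(modes):
        kx = rng.integers(1, 4)
        ky = rng.integers(1, 4)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        f += rng.normal() * np.sin(2 * np.pi * kx * x / grid.nx + ph[0]) \
            * np.cos(2 * np.pi * ky * y / grid.ny + ph[1])
    return amplitude * f / max(np.abs(f).max(), 1e-12)
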