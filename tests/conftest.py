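import numpy as np
import pytest
from hypothesis import settings

from fladmm import ImageGrid, RadonTransform, ScanGeometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_system():
    """A small well-posed CT system: 6x6 grid, 8 bins, 6 views."""
    grid = ImageGrid(6, 6)
    geom = ScanGeometry(8, 6)
    return grid, geom, RadonTransform(grid, geom)


def dense_gradient_matrix(n_x: int, n_y: int) -> np.ndarray:
    """Explicit 2N x N backward-difference matrix, assembled from the
    defining stencil (independent of the package's grad implementation):
    row block 1 = row differences (zero on the first image row), block 2 =
    column differences (zero on the first image column)."""
    N = n_x * n_y
    D = np.zeros((2 * N, N))
    idx = lambda i, j: i * n_y + j
    for i in range(n_x):
        for j in range(n_y):
            if i >= 1:
                D[idx(i, j), idx(i, j)] = 1.0
                D[idx(i, j), idx(i - 1, j)] = -1.0
            if j >= 1:
                D[N + idx(i, j), idx(i, j)] = 1.0
                D[N + idx(i, j), idx(i, j - 1)] = -1.0
    return D
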