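import warnings

import numpy as np
import pytest

from ssma import (
    ImageStack,
    SimConfig,
    build_basis_matrix,
    generate_dataset,
    make_knot_grid,
    project_images,
)
from ssma.model import normalize_columns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blocks(rng):
    """Random 30 x 12 / 30 x 10 paired blocks, column-normalized, with a
    centered unit-variance outcome."""
    X = rng.standard_normal((30, 12))
    Y = rng.standard_normal((30, 10))
    Z = rng.standard_normal(30)
    Xn, _, _ = normalize_columns(X)
    Yn, _, _ = normalize_columns(Y)
    Zc = Z - Z.mean()
    Zc = Zc / Zc.std(ddof=1)
    return Xn, Yn, Zc


@pytest.fixture(scope="session")
def small_sim_k1():
    """Shared 40x40 / 2-pixel-knot basis plus a projector for simulated data."""
    grid = make_knot_grid((40, 40), 2)
    probe = ImageStack(np.zeros((2, 1600)), (40, 40))
    basis = build_basis_matrix(probe, grid)

    def project(data):
        stack_x, stack_y = data.stacks()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return project_images(stack_x, basis), project_images(stack_y, basis)

    return basis, project


@pytest.fixture
def basis_8x8():
    stack = ImageStack(np.zeros((2, 64)), (8, 8))
    grid = make_knot_grid((8, 8), 2)
    return stack, grid, build_basis_matrix(stack, grid)
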