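import numpy as np
import pytest

from alphamorph.morphology import Skeleton
from alphamorph.synthetic import TreeParams, generate_vessel_tree


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_points(seed, n, scale=100.0):
    return np.random.default_rng(seed).uniform(0.0, scale, size=(n, 2))


@pytest.fixture
def random_points_factory():
    return random_points


@pytest.fixture
def small_tree():
    skel, _ = generate_vessel_tree(TreeParams(image_size=128, seed=42))
    return skel


def straight_line_skeleton(length, width=None):
    width = width or length + 4
    grid = np.zeros((7, width), dtype=bool)
    grid[3, 2: 2 + length] = True
    return Skeleton(grid=grid)


def ring_skeleton(radius=15):
    from skimage.draw import circle_perimeter

    size = 2 * radius + 9
    grid = np.zeros((size, size), dtype=bool)
    rr, cc = circle_perimeter(size // 2, size // 2, radius)
    grid[rr, cc] = True
    return Skeleton(grid=grid)


@pytest.fixture
def line_skeleton_factory():
    return straight_line_skeleton


@pytest.fixture
def ring_skeleton_factory():
    return ring_skeleton
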