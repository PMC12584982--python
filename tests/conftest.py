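import warnings

import numpy as np
import pytest

from stquat import QuaternionArray, RankWarning, build_grid, simulate_fig1, svd_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_quaternions(rng, shape):
    return QuaternionArray(*rng.normal(size=(4,) + tuple(shape)))


@pytest.fixture
def fig1_counts():
    return simulate_fig1()


@pytest.fixture
def fig1_quaternions(fig1_counts):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankWarning)
        return svd_model(fig1_counts)


@pytest.fixture
def small_grid(rng):
    """A fully observed 6x8 grid of unit-vector quaternions."""
    n = 48
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    depth = rng.uniform(1.0, 10.0, size=n)
    q = QuaternionArray.from_vector(depth, vec)
    xx, yy = np.meshgrid(np.arange(8.0), np.arange(6.0)[::-1])
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    return build_grid(q, coords, 6, 8, fill=False)
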