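import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def radial_field(shape=(12, 12), center=(5.5, 5.5), sign=1.0):
    """u = sign*(x - cx), v = sign*(y - cy): node field (outflow for sign>0)."""
    rows, cols = shape
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cx, cy = center
    return sign * (xx - cx), sign * (yy - cy)


def saddle_field(shape=(12, 12), center=(5.5, 5.5)):
    """u = x - cx, v = -(y - cy): saddle field (index -1)."""
    rows, cols = shape
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cx, cy = center
    return xx - cx, -(yy - cy)


def rotational_field(shape=(12, 12), center=(5.5, 5.5), sign=1.0):
    """u = -sign*(y - cy), v = sign*(x - cx): pure rotation (focus-like)."""
    rows, cols = shape
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cx, cy = center
    return -sign * (yy - cy), sign * (xx - cx)


@pytest.fixture
def grid_xy():
    def make(rows, cols):
        return np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")

    return make
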