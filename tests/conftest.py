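import math

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from rosettakit.segmentation import BinaryMask


def disc_grid(r: int, pad: int = 10) -> np.ndarray:
    n = 2 * r + 2 * pad + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


def square_grid(side: int, pad: int = 10) -> np.ndarray:
    n = side + 2 * pad
    g = np.zeros((n, n), dtype=bool)
    g[pad : pad + side, pad : pad + side] = True
    return g


def annulus_grid(outer: int, hole: int, pad: int = 10) -> np.ndarray:
    g = square_grid(outer, pad)
    lo = pad + (outer - hole) // 2
    g[lo : lo + hole, lo : lo + hole] = False
    return g


def rotated_rect_grid(width: float, height: float, angle_deg: float, size: int = 240) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    half = np.array(
        [[-height / 2, -width / 2], [-height / 2, width / 2],
         [height / 2, width / 2], [height / 2, -width / 2]]
    )
    rot = half @ np.array([[c, -s], [s, c]])
    g = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(size / 2 + rot[:, 0], size / 2 + rot[:, 1], shape=g.shape)
    g[rr, cc] = True
    return g


def star_grid(arm: int = 40, thickness: int = 10, pad: int = 10) -> np.ndarray:
    """4-armed plus/star shape."""
    n = 2 * arm + thickness + 2 * pad
    g = np.zeros((n, n), dtype=bool)
    c = n // 2
    t = thickness // 2
    g[c - t : c + t + 1, pad : n - pad] = True
    g[pad : n - pad, c - t : c + t + 1] = True
    return g


@pytest.fixture
def disc_mask() -> BinaryMask:
    return BinaryMask(disc_grid(50), 1.0)


@pytest.fixture
def square_mask() -> BinaryMask:
    return BinaryMask(square_grid(100), 1.0)


@pytest.fixture
def annulus_mask() -> BinaryMask:
    return BinaryMask(annulus_grid(100, 50), 1.0)
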