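import numpy as np
import pytest

from karyoclass.features import NucleusImage


def disk_mask(radius: int) -> np.ndarray:
    n = 2 * radius + 5
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def ellipse_mask(a: float, b: float) -> np.ndarray:
    H, W = int(np.ceil(2 * b)) + 7, int(np.ceil(2 * a)) + 7
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2, (W - 1) / 2
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1


def flat_nucleus(mask: np.ndarray, intensity: float = 100.0) -> NucleusImage:
    return NucleusImage(pixels=np.full(mask.shape, intensity), mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def constant_4x4():
    return NucleusImage(pixels=np.full((4, 4), 100.0), mask=np.ones((4, 4), bool))


@pytest.fixture
def checkerboard_4x4():
    levels = (np.indices((4, 4)).sum(axis=0) % 2) * 255.0
    return NucleusImage(pixels=levels, mask=np.ones((4, 4), bool))
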