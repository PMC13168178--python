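"""Shared synthetic-geometry helpers for the test suite."""

import numpy as np
import pytest


def _disk(size: int, radius: float, center=None) -> np.ndarray:
    if center is None:
        cy = cx = (size - 1) / 2.0
    else:
        cy, cx = center
    yy, xx = np.mgrid[0:size, 0:size]
    return (np.hypot(xx - cx, yy - cy) <= radius).astype(np.uint8)


def _star(size: int, radius: float, amplitude: float, frequency: int = 4,
          phase: float = 0.0, center=None) -> np.ndarray:
    if center is None:
        cy = cx = (size - 1) / 2.0
    else:
        cy, cx = center
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    rho = np.hypot(xx - cx, yy - cy)
    r = radius * (1.0 + amplitude * np.sin(frequency * theta + phase))
    return (rho <= r).astype(np.uint8)


@pytest.fixture
def make_disk():
    return _disk


@pytest.fixture
def make_star():
    return _star
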