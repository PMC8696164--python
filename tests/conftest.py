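import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles-style imports

from ocutrack.core import PreprocParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def scene_preproc():
    """Preprocessing matched to the synthetic renderer's intensity levels."""
    return PreprocParams(threshold=95.0, invert=True, cr_threshold=200.0)


def circle_points(n, cx=0.0, cy=0.0, r=10.0, phase=0.0):
    t = np.linspace(0.0, 2.0 * math.pi, n + 1)[:-1] + phase
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def ellipse_points(n, cx, cy, a, b, theta, phase=0.0):
    t = np.linspace(0.0, 2.0 * math.pi, n + 1)[:-1] + phase
    ct, st = math.cos(theta), math.sin(theta)
    x = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    y = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.column_stack([x, y])


def disk_image(shape, cx, cy, r):
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r).astype(np.uint8)
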