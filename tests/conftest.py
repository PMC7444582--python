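import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from spermacal import FrameStack


def textured_frame(rng, shape=(48, 48), lo=20, hi=220):
    """A smooth, high-contrast random frame suitable for registration."""
    from scipy.ndimage import gaussian_filter

    raw = gaussian_filter(rng.random(shape), sigma=1.2)
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    return (lo + raw * (hi - lo)).astype(np.uint8)


def shifted_copy(frame, dy, dx, fill=None):
    """Translate frame content by (dy, dx), filling exposed edges."""
    H, W = frame.shape
    out = np.full_like(frame, int(np.median(frame)) if fill is None else fill)
    ay0, ay1 = max(0, dy), min(H, H + dy)
    ax0, ax1 = max(0, dx), min(W, W + dx)
    out[ay0:ay1, ax0:ax1] = frame[ay0 - dy:ay1 - dy, ax0 - dx:ax1 - dx]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_stack(rng):
    return FrameStack(
        pixels=rng.integers(0, 256, size=(10, 32, 64), dtype=np.uint8),
        dt=1.0,
        bit_depth=8,
    )
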