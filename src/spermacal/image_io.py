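"""Image-stack I/O and rigid integer-shift registration.

Time-lapse recordings of the paralyzed animal are stored as multi-page
grayscale TIFF stacks (8- or 16-bit, fixed frame interval).  Before any
intensity is measured the stack is registered to its first frame to remove
residual body movement; registration here is integer-pixel translation only,
found by exhaustive zero-normalized cross-correlation against frame 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["FrameStack", "ShiftSeries", "read_stack", "write_stack", "register_stack"]

_ALLOWED_DEPTHS = (8, 16)


@dataclass
class FrameStack:
    """A T x H x W grayscale movie with a fixed frame interval.

    Parameters
    ----------
    pixels
        Non-negative integer array of shape (T, H, W).
    dt
        Frame interval in seconds (1.0 for the standard 1 frame/s acquisition).
    bit_depth
        8 or 16; pixel values must fit the depth.
    provenance
        Free-text record of where the stack came from (file path, simulator
        parameters, intensity mapping ...).
    """

    pixels: np.ndarray
    dt: float = 1.0
    bit_depth: int = 8
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be T x H x W, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_ALLOWED_DEPTHS}, got {self.bit_depth}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel values must be non-negative")
        if self.pixels.size and self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel value {self.pixels.max()} exceeds {self.bit_depth}-bit range"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclass
class ShiftSeries:
    """Per-frame integer (dy, dx) displacement relative to frame 0."""

    shifts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shifts and tuple(self.shifts[0]) != (0, 0):
            raise ValueError("shift of frame 0 must be (0, 0)")

    def __iter__(self):
        return iter(self.shifts)

    def __len__(self) -> int:
        return len(self.shifts)

    def __getitem__(self, i: int) -> tuple[int, int]:
        return self.shifts[i]


def read_stack(path, dt: float = 1.0) -> FrameStack:
    """Read a multi-page grayscale TIFF into a :class:`FrameStack`.

    Every page must be 2-D (grayscale) and all pages must share one frame
    size; violations are reported with the 1-based offending page number.
    """
    with tifffile.TiffFile(str(path)) as tif:
        frames = []
        shape0 = None
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"page {i + 1} of {path} is not grayscale (shape {arr.shape})"
                )
            if shape0 is None:
                shape0 = arr.shape
            elif arr.shape != shape0:
                raise ValueError(
                    f"page {i + 1} of {path} has size {arr.shape}, "
                    f"but page 1 has {shape0}"
                )
            frames.append(arr)
    if not frames:
        raise ValueError(f"{path} contains no image pages")
    pixels = np.stack(frames)
    if pixels.dtype == np.uint8:
        depth = 8
    elif pixels.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported pixel type {pixels.dtype} in {path}")
    return FrameStack(pixels=pixels, dt=dt, bit_depth=depth, provenance=f"read from {path}")


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF (lossless round trip)."""
    tifffile.imwrite(str(path), stack.pixels.astype(stack.dtype), photometric="minisblack")


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape regions."""
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return -np.inf
    return float((a @ b) / denom)


def _best_shift(ref: np.ndarray, frame: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (dy, dx) displacement of `frame` content relative to `ref`.

    Exhaustive search over the +/- max_shift window; ties on correlation are
    broken by smallest |dy|+|dx|, then lexicographically on (dy, dx).
    """
    H, W = ref.shape
    best = (0, 0)
    best_score = -np.inf
    # candidates ordered so the tie-break is simply "first wins"
    candidates = sorted(
        ((dy, dx) for dy in range(-max_shift, max_shift + 1)
         for dx in range(-max_shift, max_shift + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), s),
    )
    for dy, dx in candidates:
        ay0, ay1 = max(0, -dy), min(H, H - dy)
        ax0, ax1 = max(0, -dx), min(W, W - dx)
        if ay1 <= ay0 or ax1 <= ax0:
            continue
        score = _zncc(ref[ay0:ay1, ax0:ax1],
                      frame[ay0 + dy:ay1 + dy, ax0 + dx:ax1 + dx])
        if score > best_score + 1e-12:
            best_score = score
            best = (dy, dx)
    return best


def _apply_shift(frame: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    """Undo a (dy, dx) content displacement, padding exposed edges with `fill`."""
    H, W = frame.shape
    out = np.full_like(frame, fill)
    ay0, ay1 = max(0, -dy), min(H, H - dy)
    ax0, ax1 = max(0, -dx), min(W, W - dx)
    if ay1 > ay0 and ax1 > ax0:
        out[ay0:ay1, ax0:ax1] = frame[ay0 + dy:ay1 + dy, ax0 + dx:ax1 + dx]
    return out


def register_stack(stack: FrameStack, max_shift: int = 10) -> tuple[FrameStack, ShiftSeries]:
    """Align every frame to frame 0 by integer translation.

    For each frame the (dy, dx) within +/- max_shift maximizing the
    zero-normalized cross-correlation with frame 0 is found and undone;
    pixels exposed at the edges are filled with that frame's median, which
    avoids dragging ROI means toward zero.  A constant (zero-variance) frame
    cannot be correlated and keeps shift (0, 0) with a warning.
    """
    H, W = stack.frame_shape
    if max_shift >= min(H, W) / 4:
        raise ValueError(f"max_shift {max_shift} must be < min(H, W)/4 = {min(H, W) / 4}")
    ref = stack.pixels[0].astype(np.float64)
    shifts: list[tuple[int, int]] = [(0, 0)]
    aligned = [stack.pixels[0].copy()]
    for t in range(1, stack.n_frames):
        frame = stack.pixels[t]
        if frame.max() == frame.min():
            warnings.warn(f"frame {t} is constant; shift fixed at (0, 0)", stacklevel=2)
            shifts.append((0, 0))
            aligned.append(frame.copy())
            continue
        dy, dx = _best_shift(ref, frame.astype(np.float64), max_shift)
        shifts.append((dy, dx))
        fill = int(np.median(frame))
        aligned.append(_apply_shift(frame, dy, dx, fill))
    out = FrameStack(
        pixels=np.stack(aligned),
        dt=stack.dt,
        bit_depth=stack.bit_depth,
        provenance=stack.provenance + " | registered to frame 0",
    )
    return out, ShiftSeries(shifts)
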