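"""ROI traces, F/F0 normalization, and kymograms.

The GCaMP signal of one spermatheca is summarized per frame as the
arithmetic mean of a rectangular ROI.  Intensities are reported as F/F0,
where F0 is the mean intensity of the 30 frames immediately preceding the
start of oocyte entry (fewer when the recording starts late, with a
warning).  Kymograms collapse each frame to one row of per-column means so
that propagating Ca2+ waves appear as sloped streaks.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .image_io import FrameStack
from .transit_annotation import EventRecord

__all__ = [
    "ROISpec",
    "CalciumTrace",
    "Kymogram",
    "extract_trace",
    "normalize_trace",
    "build_kymogram",
    "write_trace_csv",
    "read_trace_csv",
    "write_kymogram_csv",
    "write_kymogram_tiff",
]

DEFAULT_BASELINE_LEN = 30


@dataclass
class ROISpec:
    """Rectangular region of interest, 0-based and half-open on both axes."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI top/left must be >= 0")

    def validate_against(self, frame_shape: tuple[int, int]) -> None:
        H, W = frame_shape
        if self.top + self.height > H:
            raise ValueError(
                f"ROI bottom {self.top + self.height} exceeds frame height {H}"
            )
        if self.left + self.width > W:
            raise ValueError(
                f"ROI right edge {self.left + self.width} exceeds frame width {W}"
            )

    @classmethod
    def full_frame(cls, stack: FrameStack) -> "ROISpec":
        H, W = stack.frame_shape
        return cls(0, 0, H, W)


@dataclass
class CalciumTrace:
    """A normalized per-frame intensity series with its event annotations."""

    t: np.ndarray          # seconds per sample
    F_raw: np.ndarray      # mean ROI intensity per frame
    F0: float              # baseline, mean-intensity units
    F_norm: np.ndarray     # F_raw / F0, dimensionless
    events: EventRecord | None = None
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.F_raw = np.asarray(self.F_raw, dtype=np.float64)
        self.F_norm = np.asarray(self.F_norm, dtype=np.float64)
        if not (len(self.t) == len(self.F_raw) == len(self.F_norm)):
            raise ValueError("t, F_raw and F_norm must have equal length")
        if self.F0 <= 0:
            raise ValueError(f"F0 must be positive, got {self.F0}")

    def __len__(self) -> int:
        return len(self.F_raw)


@dataclass
class Kymogram:
    """T x W space-time matrix; one row per frame, distal left, valve right."""

    values: np.ndarray
    dt: float = 1.0
    orientation: str = "distal_left_valve_right"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"kymogram must be 2-D, got shape {self.values.shape}")


def extract_trace(stack: FrameStack, roi: ROISpec) -> np.ndarray:
    """Mean ROI intensity per frame (float64, one value per frame)."""
    roi.validate_against(stack.frame_shape)
    block = stack.pixels[:, roi.top:roi.top + roi.height, roi.left:roi.left + roi.width]
    return block.mean(axis=(1, 2), dtype=np.float64)


def normalize_trace(
    raw: np.ndarray,
    entry_frame: int,
    baseline_len: int = DEFAULT_BASELINE_LEN,
    dt: float = 1.0,
    events: EventRecord | None = None,
) -> CalciumTrace:
    """Normalize a raw trace to the pre-entry baseline F0.

    F0 is the mean of the `baseline_len` frames immediately preceding
    `entry_frame`; when fewer pre-entry frames exist the window shrinks to
    what is available and a warning is emitted.  An entry at frame 0 (no
    pre-entry data) or a zero baseline is an error.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("raw trace is empty")
    if entry_frame < 1:
        raise ValueError("entry_frame must be >= 1: no pre-entry baseline frames exist")
    w = min(baseline_len, entry_frame)
    if w < baseline_len:
        warnings.warn(
            f"only {w} pre-entry frames available; baseline window shrunk from "
            f"{baseline_len} to {w}",
            stacklevel=2,
        )
    F0 = float(raw[entry_frame - w:entry_frame].mean())
    if F0 == 0.0:
        raise ValueError("baseline F0 is zero; trace cannot be normalized")
    t = np.arange(raw.size, dtype=np.float64) * dt
    if events is None:
        events = EventRecord(entry_start=entry_frame, observation_end=raw.size - 1)
    return CalciumTrace(t=t, F_raw=raw, F0=F0, F_norm=raw / F0, events=events, dt=dt)


def build_kymogram(
    stack: FrameStack,
    roi: ROISpec,
    normalize_by: float | None = None,
) -> Kymogram:
    """Column-mean kymogram of the ROI: entry (t, x) = mean over ROI rows.

    Computed on raw intensities by default; pass `normalize_by=F0` for the
    normalized variant.  Row means of the result equal the frame ROI means
    exactly (all columns carry equal weight).
    """
    roi.validate_against(stack.frame_shape)
    block = stack.pixels[:, roi.top:roi.top + roi.height, roi.left:roi.left + roi.width]
    values = block.mean(axis=1, dtype=np.float64)
    if normalize_by is not None:
        if normalize_by <= 0:
            raise ValueError(f"normalize_by must be positive, got {normalize_by}")
        values = values / normalize_by
    return Kymogram(values=values, dt=stack.dt, normalized=normalize_by is not None)


def write_trace_csv(trace: CalciumTrace, path) -> None:
    """Write frame,time_s,F_raw,F_norm rows under '# key=value' metadata lines."""
    ev = trace.events
    buf = io.StringIO()
    buf.write(f"# F0={trace.F0!r}\n")
    buf.write(f"# dt={trace.dt!r}\n")
    if ev is not None and ev.entry_start is not None:
        buf.write(f"# entry_frame={ev.entry_start}\n")
    for name in ("neck_close", "valve_open", "valve_close"):
        val = getattr(ev, name) if ev is not None else None
        if val is not None:
            buf.write(f"# {name}={val}\n")
    df = pd.DataFrame(
        {
            "frame": np.arange(len(trace)),
            "time_s": trace.t,
            "F_raw": trace.F_raw,
            "F_norm": trace.F_norm,
        }
    )
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trace_csv(path) -> CalciumTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    ev = EventRecord(
        entry_start=int(meta["entry_frame"]) if "entry_frame" in meta else None,
        neck_close=int(meta["neck_close"]) if "neck_close" in meta else None,
        valve_open=int(meta["valve_open"]) if "valve_open" in meta else None,
        valve_close=int(meta["valve_close"]) if "valve_close" in meta else None,
        observation_end=len(df) - 1,
    )
    return CalciumTrace(
        t=df["time_s"].to_numpy(),
        F_raw=df["F_raw"].to_numpy(),
        F0=float(meta["F0"]),
        F_norm=df["F_norm"].to_numpy(),
        events=ev,
        dt=float(meta.get("dt", 1.0)),
    )


def write_kymogram_csv(kymo: Kymogram, path) -> None:
    np.savetxt(path, kymo.values, delimiter=",", fmt="%.12g")


def write_kymogram_tiff(kymo: Kymogram, path) -> None:
    """Render the kymogram as a single-page float32 TIFF image."""
    tifffile.imwrite(str(path), kymo.values.astype(np.float32), photometric="minisblack")
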