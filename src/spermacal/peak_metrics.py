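"""Smoothing, prominence/width peak detection, and pulse metrics.

Normalized traces are smoothed with a centered 5-point moving average and
peaks are kept when their topographic prominence reaches 0.1 normalized
units and their width at half prominence reaches 5 samples (= 5 s at the
1 frame/s acquisition rate).  From the surviving peaks the per-transit
metrics are derived: peak count, peaks per second of transit, time after
entry to half-maximal and to maximal signal, and the variance of the first
derivative as a scalar flatness statistic.

Definitions (all deterministic):

* a candidate maximum is a sample strictly greater than both neighbours; a
  flat plateau counts once, at its middle sample (left-middle when even);
* prominence = peak value - max(left base, right base), where each base is
  the minimum of the signal between the peak and the nearer of the signal
  end or the next sample strictly exceeding the peak, on that side;
* width = horizontal extent at height (value - prominence/2), found by
  linear interpolation and clipped to the base interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .trace_pipeline import CalciumTrace

__all__ = [
    "AnalysisParams",
    "Peak",
    "PulseMetrics",
    "smooth",
    "find_peaks",
    "compute_metrics",
    "derivative_variance",
    "metrics_to_json",
]


@dataclass
class AnalysisParams:
    """Detection settings; the defaults are the standardized analysis values."""

    smooth_window: int = 5       # samples, centered moving average
    min_prominence: float = 0.1  # normalized F/F0 units
    min_width: float = 5.0       # samples (seconds at 1 frame/s)
    fps: float = 1.0             # frames per second

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError(f"smooth_window must be odd and >= 1, got {self.smooth_window}")
        if self.min_prominence < 0:
            raise ValueError(f"min_prominence must be >= 0, got {self.min_prominence}")
        if self.min_width < 1:
            raise ValueError(f"min_width must be >= 1, got {self.min_width}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")


@dataclass
class Peak:
    index: int          # sample index in the analysed trace
    time: float         # seconds
    value: float        # normalized units
    prominence: float   # normalized units
    width: float        # samples at half-prominence height


@dataclass
class PulseMetrics:
    n_peaks: int
    peaks_per_second: float
    t_half_max: float | None   # s after entry, None when no peak passes
    t_max: float | None        # s after entry
    deriv_variance: float      # (normalized units / sample)^2


def smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window truncates at the trace edges."""
    x = np.asarray(x, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds trace length {x.size}")
    half = window // 2
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(x.size, idx + half + 1)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _plateau_maxima(x: np.ndarray) -> list[int]:
    """Indices of local maxima; a flat plateau is reported at its middle."""
    n = x.size
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def _prominence(x: np.ndarray, p: int) -> tuple[float, int, int]:
    """Prominence of peak p plus the argmin base positions on both sides."""
    v = x[p]
    # left side: scan to the next strictly higher sample or the signal start
    i = p - 1
    left_base = p
    while i >= 0 and x[i] <= v:
        if x[i] < x[left_base]:
            left_base = i
        i -= 1
    j = p + 1
    right_base = p
    while j < x.size and x[j] <= v:
        if x[j] < x[right_base]:
            right_base = j
        j += 1
    prom = v - max(x[left_base], x[right_base])
    return float(prom), left_base, right_base


def _width(x: np.ndarray, p: int, prom: float, lb: int, rb: int) -> float:
    """Width at height value - prom/2, linear interpolation, clipped to bases."""
    h = x[p] - prom / 2.0
    i = p
    while i > lb and x[i - 1] > h:
        i -= 1
    if i == lb:
        left = float(lb)
    else:
        # crossing lies between x[i-1] <= h and x[i] > h
        left = i - (x[i] - h) / (x[i] - x[i - 1])
    j = p
    while j < rb and x[j + 1] > h:
        j += 1
    if j == rb:
        right = float(rb)
    else:
        right = j + (x[j] - h) / (x[j] - x[j + 1])
    return right - left


def find_peaks(x: np.ndarray, params: AnalysisParams | None = None, dt: float = 1.0) -> list[Peak]:
    """Detect peaks by prominence and width on an (already smoothed) trace.

    Returns peaks sorted by index; an empty list is a valid result.  The
    trace must contain at least 3 samples.
    """
    params = params or AnalysisParams()
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"trace must have >= 3 samples, got {x.size}")
    out = []
    for p in _plateau_maxima(x):
        prom, lb, rb = _prominence(x, p)
        if prom < params.min_prominence:
            continue
        w = _width(x, p, prom, lb, rb)
        if w < params.min_width:
            continue
        out.append(Peak(index=p, time=p * dt, value=float(x[p]), prominence=prom, width=w))
    return out


def derivative_variance(x: np.ndarray) -> float:
    """Sample variance (n-1 denominator) of the successive differences.

    A scalar 'flatness' statistic: flat or linearly drifting traces score 0,
    pulsing traces score high.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"trace must have >= 3 samples, got {x.size}")
    return float(np.var(np.diff(x), ddof=1))


def compute_metrics(
    trace: CalciumTrace,
    params: AnalysisParams | None = None,
    half_max_mode: str = "absolute",
) -> PulseMetrics:
    """Pulse metrics of one transit, computed on the smoothed F/F0 trace.

    Peaks are detected on the smoothed trace restricted to the transit
    window [entry_start, valve_close] (through the recording end when the
    valve never closes); the rate denominator is the same duration.  t_max
    is the time from entry to the highest-valued detected peak (earliest on
    ties); t_half_max is the time from entry to the first smoothed sample at
    or above half that peak value (`half_max_mode="baseline_subtracted"`
    instead thresholds halfway between the 1.0 baseline and the peak).
    Both are None when no peak passes the filters.  The derivative variance
    is computed on the full unsmoothed normalized trace.
    """
    params = params or AnalysisParams()
    if trace.events is None or trace.events.entry_start is None:
        raise ValueError("trace has no entry annotation; metrics are entry-anchored")
    if half_max_mode not in ("absolute", "baseline_subtracted"):
        raise ValueError(f"unknown half_max_mode {half_max_mode!r}")
    dt = trace.dt
    entry = trace.events.entry_start
    end = trace.events.valve_close if trace.events.valve_close is not None else len(trace) - 1
    smoothed = smooth(trace.F_norm, params.smooth_window)
    segment = smoothed[entry:end + 1]
    peaks = find_peaks(segment, params, dt=dt) if segment.size >= 3 else []
    duration = (end - entry) * dt
    n = len(peaks)
    rate = n / duration if duration > 0 else 0.0
    if n == 0:
        t_half = t_max = None
    else:
        best = max(peaks, key=lambda p: (p.value, -p.index))
        t_max = best.index * dt
        if half_max_mode == "absolute":
            threshold = best.value / 2.0
        else:
            threshold = 1.0 + (best.value - 1.0) / 2.0
        crossing = np.nonzero(segment >= threshold)[0]
        t_half = float(crossing[0]) * dt if crossing.size else None
    return PulseMetrics(
        n_peaks=n,
        peaks_per_second=rate,
        t_half_max=t_half,
        t_max=t_max,
        deriv_variance=derivative_variance(trace.F_norm),
    )


def metrics_to_json(metrics: PulseMetrics) -> str:
    return json.dumps(asdict(metrics), indent=2)
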