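"""Synthetic spatiotemporal Ca2+ movies with ground truth.

The spermatheca is modelled as a 1-D strip of tissue: distal neck at column
0, central bag in between, and the sp-ut valve occupying the proximal-most
10% of columns.  Ca2+ pulses are unit-peak Gaussian kernels launched at the
distal end at regular intervals after oocyte entry and propagating toward
the valve at a fixed wave speed, so a pulse appears at position x (in
tissue lengths) with a delay x/v.  The field is

    F(x, t) = B + eps(t, x) + sum_i A0 * (1 + r*(t_i - t_entry)) * g((t - t_i - x/v)/tau)

with g a unit-peak Gaussian, pulse onsets t_i = t_entry + D + i*P, and
eps i.i.d. Gaussian noise.  The valve columns follow one of four regimes
observed across genotypes: a bright spike on entry then quiet (wild type),
sustained high signal, fully suppressed, or pulsing in register with the
bag.  Each simulation also emits the event annotations and phenotype label
of the underlying ovulation, so the entire downstream pipeline can be
validated against known ground truth.

Presets for seven genotype-like regimes ship as JSON files under
``spermacal/presets``; their parameter values are this package's choices of
realistic dynamics, not measured constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from .image_io import FrameStack
from .transit_annotation import EventRecord, TransitPhenotype

__all__ = [
    "GenotypePreset",
    "SpatioTemporalField",
    "GroundTruth",
    "VALVE_REGIMES",
    "simulate_field",
    "render_movie",
    "load_preset",
    "available_presets",
    "VALVE_FRACTION",
]

VALVE_REGIMES = (
    "entry_spike_then_quiet",
    "sustained_high",
    "suppressed",
    "pulsing_with_bag",
)

#: fraction of columns assigned to the sp-ut valve (4 valve cells vs 24 bag
#: cells -> order 10%)
VALVE_FRACTION = 0.1

#: amplitude of the valve's entry spike, normalized units above baseline
ENTRY_SPIKE_AMPLITUDE = 1.0

#: plateau height of the sustained-high valve regime, normalized units
SUSTAINED_HIGH_LEVEL = 1.0


@dataclass
class GenotypePreset:
    """Parameters of one simulated dynamic regime.

    Attributes
    ----------
    baseline : normalized units, the pre-entry F/F0 level (about 1.0).
    noise_sd : per-pixel Gaussian noise sd, normalized units.
    onset_delay : seconds between oocyte entry and the first pulse.
    pulse_period : seconds between successive pulse onsets.
    pulse_amplitude : peak height of the first pulse above baseline.
    ramp_rate : fractional amplitude growth per second since entry
        (pulse i has amplitude A0 * (1 + r * (t_i - t_entry))).
    wave_speed : tissue lengths per second of distal-to-proximal propagation.
    pulse_tau : Gaussian kernel time constant, seconds.
    valve_regime : one of VALVE_REGIMES.
    entry_frame .. neck_close_frame : annotated event frames; None = absent
        (an empty spermatheca has no entry and pulses are timed from t=0).
    exit_outcome : TransitPhenotype of the simulated ovulation, or None when
        no transit occurs.
    """

    name: str
    baseline: float = 1.0
    noise_sd: float = 0.02
    onset_delay: float = 0.0
    pulse_period: float = 30.0
    pulse_amplitude: float = 0.5
    ramp_rate: float = 0.0
    wave_speed: float = 0.1
    pulse_tau: float = 5.0
    valve_regime: str = "suppressed"
    entry_frame: int | None = None
    neck_close_frame: int | None = None
    valve_open_frame: int | None = None
    valve_close_frame: int | None = None
    exit_outcome: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.pulse_amplitude > 0 and self.pulse_period <= 0:
            raise ValueError(
                f"pulse_period must be > 0 when pulse_amplitude > 0, got {self.pulse_period}"
            )
        if self.onset_delay < 0:
            raise ValueError(f"onset_delay must be >= 0, got {self.onset_delay}")
        if self.pulse_tau <= 0:
            raise ValueError(f"pulse_tau must be > 0, got {self.pulse_tau}")
        if self.wave_speed <= 0:
            raise ValueError(f"wave_speed must be > 0, got {self.wave_speed}")
        if self.valve_regime not in VALVE_REGIMES:
            raise ValueError(
                f"valve_regime {self.valve_regime!r} not one of {VALVE_REGIMES}"
            )
        if self.exit_outcome is not None:
            TransitPhenotype(self.exit_outcome)  # raises on unknown label


@dataclass
class SpatioTemporalField:
    """T x X matrix of normalized intensity; distal at column 0, valve last."""

    values: np.ndarray
    dt: float = 1.0
    x_convention: str = "distal_at_0_valve_at_end"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError(f"field must be T x X with T >= 1, X >= 2, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    pulse_onsets: list[float] = field(default_factory=list)
    events: EventRecord = field(default_factory=EventRecord)
    phenotype_label: TransitPhenotype | None = None

    @property
    def pulse_count(self) -> int:
        return len(self.pulse_onsets)


def _pulse_onsets(preset: GenotypePreset, t_entry: float, duration: float) -> list[float]:
    if preset.pulse_amplitude <= 0:
        return []
    onsets = []
    t_i = t_entry + preset.onset_delay
    while t_i < duration:
        onsets.append(t_i)
        t_i += preset.pulse_period
    return onsets


def n_valve_columns(n_columns: int) -> int:
    return max(1, int(round(VALVE_FRACTION * n_columns)))


def simulate_field(
    preset: GenotypePreset,
    duration: float,
    seed: int,
    n_columns: int = 40,
    dt: float = 1.0,
) -> tuple[SpatioTemporalField, GroundTruth]:
    """Simulate the normalized Ca2+ field for one recording.

    Returns the T x X field (T = round(duration/dt) frames) and the ground
    truth: the exact pulse onset times emitted, the event annotations from
    the preset, and its phenotype label.  A fixed (preset, duration, seed)
    triple is bit-reproducible.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if duration < preset.onset_delay:
        raise ValueError(
            f"duration {duration} is shorter than onset_delay {preset.onset_delay}"
        )
    T = int(round(duration / dt))
    X = int(n_columns)
    if X < 2:
        raise ValueError(f"n_columns must be >= 2, got {n_columns}")
    n_valve = n_valve_columns(X)
    n_bag = X - n_valve
    t = np.arange(T, dtype=np.float64) * dt

    t_entry = preset.entry_frame * dt if preset.entry_frame is not None else 0.0
    onsets = _pulse_onsets(preset, t_entry, duration)

    # bag columns at positions 0..1 tissue lengths (distal -> proximal)
    x_bag = np.linspace(0.0, 1.0, n_bag)
    values = np.full((T, X), preset.baseline, dtype=np.float64)
    for t_i in onsets:
        amp = preset.pulse_amplitude * (1.0 + preset.ramp_rate * (t_i - t_entry))
        arg = (t[:, None] - t_i - x_bag[None, :] / preset.wave_speed) / preset.pulse_tau
        values[:, :n_bag] += amp * np.exp(-0.5 * arg**2)

    # valve block (proximal-most columns) follows its own regime
    valve = np.full(T, preset.baseline, dtype=np.float64)
    if preset.valve_regime == "entry_spike_then_quiet":
        valve += ENTRY_SPIKE_AMPLITUDE * np.exp(
            -0.5 * ((t - t_entry) / preset.pulse_tau) ** 2
        )
    elif preset.valve_regime == "sustained_high":
        valve += SUSTAINED_HIGH_LEVEL * (t >= t_entry)
    elif preset.valve_regime == "pulsing_with_bag":
        for t_i in onsets:
            amp = preset.pulse_amplitude * (1.0 + preset.ramp_rate * (t_i - t_entry))
            valve += amp * np.exp(
                -0.5 * ((t - t_i - 1.0 / preset.wave_speed) / preset.pulse_tau) ** 2
            )
    # "suppressed": stays at baseline
    values[:, n_bag:] = valve[:, None]

    if preset.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, preset.noise_sd, size=(T, X))

    outcome = TransitPhenotype(preset.exit_outcome) if preset.exit_outcome else None
    events = EventRecord(
        entry_start=preset.entry_frame,
        neck_close=preset.neck_close_frame,
        valve_open=preset.valve_open_frame,
        valve_close=preset.valve_close_frame,
        embryo_exited=outcome is TransitPhenotype.EXITED_SUCCESSFULLY,
        returned_to_gonad=outcome is TransitPhenotype.RETURNED_TO_GONAD_ARM,
        observation_end=T - 1,
    )
    truth = GroundTruth(pulse_onsets=onsets, events=events, phenotype_label=outcome)
    return SpatioTemporalField(values=values, dt=dt), truth


def render_movie(
    fld: SpatioTemporalField,
    height: int = 20,
    width: int = 80,
    bit_depth: int = 8,
    scale: float = 100.0,
    offset: float = 0.0,
) -> FrameStack:
    """Render the field as a grayscale movie (inverse of kymogram extraction).

    Each field column becomes a block of pixel columns (blocks differ by at
    most one pixel in width); the intensity map is affine,
    gray = round(value * scale + offset), and is recorded in the stack's
    provenance so it can be inverted.  Values that would clip at the chosen
    bit depth are rejected.
    """
    T, X = fld.values.shape
    if width < X:
        raise ValueError(f"width {width} must be >= number of field columns {X}")
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    gray = fld.values * scale + offset
    gmax, gmin = float(gray.max()), float(gray.min())
    limit = 2**bit_depth - 1
    if np.rint(gmax) > limit or np.rint(gmin) < 0:
        raise ValueError(
            f"intensity map clips at {bit_depth}-bit: mapped range "
            f"[{gmin:.2f}, {gmax:.2f}] outside [0, {limit}]"
        )
    base, rem = divmod(width, X)
    col_counts = np.full(X, base, dtype=int)
    col_counts[:rem] += 1
    rows = np.repeat(np.rint(gray), col_counts, axis=1)  # T x width
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    pixels = np.broadcast_to(rows[:, None, :], (T, height, width)).astype(dtype)
    return FrameStack(
        pixels=pixels.copy(),
        dt=fld.dt,
        bit_depth=bit_depth,
        provenance=f"rendered from field; intensity map gray=round(value*{scale}+{offset})",
    )


def _preset_dir():
    return resources.files("spermacal") / "presets"


def available_presets() -> list[str]:
    """Names of the shipped genotype-like presets."""
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".json"))


def load_preset(name: str) -> GenotypePreset:
    """Load a shipped preset by name, or any preset from a JSON path."""
    path = Path(str(name))
    if path.suffix == ".json" and path.exists():
        data = json.loads(path.read_text())
    else:
        res = _preset_dir() / f"{name}.json"
        try:
            data = json.loads(res.read_text())
        except FileNotFoundError:
            raise KeyError(
                f"unknown preset {name!r}; available: {available_presets()}"
            ) from None
    return GenotypePreset(**data)


def preset_to_json(preset: GenotypePreset) -> str:
    return json.dumps(asdict(preset), indent=2)
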