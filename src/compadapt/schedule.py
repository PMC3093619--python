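"""Frame-exact on/off timelines for compound and component adaptors.

Every adaptor in the paradigm is a pair of component gratings whose
presentation follows a square on/off cycle locked to the monitor refresh
(85 Hz by default).  Four schedule families cover the three experiments:

* ``phase_offset`` - both components cycle at the base frequency with a
  50% duty cycle; the second component's cycle is delayed by a
  frame-quantized temporal phase offset (0 deg = synchronous plaid/contour,
  180 deg = strict alternation).
* ``alternation`` - the components strictly alternate (A on while B off)
  at a configurable rate; no frame has both on.
* ``synchronous_flicker`` - both components turn on and off together,
  alternating with a blank screen.
* ``component_field`` - the control hemi-field: the two components in
  strict alternation, optionally with a whole-frame lag so its temporal
  phase is decorrelated from the compound field.

All timing is quantized to whole frames by rounding the half-period to the
nearest frame (ties to even).  A nominal 1 Hz cycle at 85 Hz therefore
realises a 42-frame (494 ms) half-period - "just over 1 Hz" - which is how
the printed condition timings (47/106/200/400/800 ms and 59/118/247/494 ms)
arise from the degree-valued phase offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Mode",
    "ScheduleSpec",
    "FrameSequence",
    "ExposureStats",
    "DEFAULT_FRAME_RATE",
    "half_period_frames",
    "phase_offset_to_ms",
    "build_phase_offset_schedule",
    "build_alternation_schedule",
    "build_flicker_schedule",
    "build_component_field_schedule",
    "build_schedule",
    "exposure_stats",
    "common_cycle_duration",
    "timeline_frame",
]

#: Monitor refresh rate used in the experiments, Hz.
DEFAULT_FRAME_RATE = 85.0


class Mode(str, Enum):
    PHASE_OFFSET = "phase_offset"
    ALTERNATION = "alternation"
    SYNCHRONOUS_FLICKER = "synchronous_flicker"
    COMPONENT_FIELD = "component_field"


@dataclass(frozen=True)
class ScheduleSpec:
    """Parameters of one adaptor timeline.

    ``base_frequency`` is the frequency of each component's on/off cycle in
    Hz; it must not exceed the Nyquist limit ``frame_rate / 2``.
    ``phase_offset`` (degrees of cycle) applies only to the phase-offset
    mode.  ``duration`` is in seconds.
    """

    mode: Mode
    base_frequency: float
    duration: float
    phase_offset: float = 0.0
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")
        if self.base_frequency > self.frame_rate / 2.0 + 1e-9:
            raise ValueError(
                f"base_frequency {self.base_frequency} Hz exceeds the Nyquist "
                f"limit {self.frame_rate / 2} Hz at {self.frame_rate} Hz refresh"
            )
        if not 0.0 <= self.phase_offset < 360.0:
            raise ValueError("phase_offset must lie in [0, 360) degrees")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class FrameSequence:
    """Per-frame on/off state of the two components of one adaptor."""

    frame_rate: float
    states: np.ndarray  # (n_frames, 2) bool: column 0 = A, column 1 = B

    @property
    def a(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def b(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSequence):
            return NotImplemented
        return (
            self.frame_rate == other.frame_rate
            and self.states.shape == other.states.shape
            and bool(np.array_equal(self.states, other.states))
        )


def half_period_frames(frequency: float, frame_rate: float = DEFAULT_FRAME_RATE) -> int:
    """Half-period of an on/off cycle in whole frames (nearest, ties to even).

    The realized cycle is ``2 * half_period_frames`` frames, so the realized
    frequency can differ slightly from the nominal one, exactly as on real
    display hardware (e.g. nominal 1 Hz at 85 Hz refresh -> 42-frame half
    period -> 85/84 ~ 1.012 Hz).
    """
    half = int(np.round(frame_rate / (2.0 * frequency)))
    if half < 1:
        raise ValueError(
            f"frequency {frequency} Hz not representable at {frame_rate} Hz refresh"
        )
    return half


def phase_offset_to_ms(
    offset_deg: float, cycle_ms: float, frame_rate: float = DEFAULT_FRAME_RATE
) -> int:
    """Convert a temporal phase offset to integer milliseconds, frame-quantized.

    ``offset/360 * cycle_ms`` is rounded to the nearest whole frame at the
    given refresh rate, and that frame count is reported as the nearest
    integer millisecond - the arithmetic behind the printed condition
    timings (e.g. 19 deg of a 2000 ms cycle at 85 Hz -> 9 frames -> 106 ms).
    """
    if cycle_ms <= 0:
        raise ValueError("cycle_ms must be positive")
    frame_ms = 1000.0 / frame_rate
    frames = int(np.round(offset_deg / 360.0 * cycle_ms / frame_ms))
    return int(np.round(frames * frame_ms))


def _n_frames(spec: ScheduleSpec) -> int:
    return int(round(spec.duration * spec.frame_rate))


def _square_wave(n: int, period: int, half: int, lag: int = 0) -> np.ndarray:
    """Boolean square wave: on for ``half`` frames at the start of each
    ``period``-frame cycle, delayed by ``lag`` frames (circular)."""
    t = np.arange(n)
    return ((t - lag) % period) < half


def build_phase_offset_schedule(spec: ScheduleSpec) -> FrameSequence:
    """Both components cycle at the base frequency; B lags A by the offset.

    The offset in degrees of cycle is quantized to the nearest whole frame.
    An offset of 180 deg yields strict alternation, frame-for-frame identical
    to :func:`build_alternation_schedule` at the same frequency.
    """
    if spec.mode is not Mode.PHASE_OFFSET:
        raise ValueError(f"spec.mode must be phase_offset, got {spec.mode}")
    half = half_period_frames(spec.base_frequency, spec.frame_rate)
    period = 2 * half
    lag = int(np.round(spec.phase_offset / 360.0 * period))
    n = _n_frames(spec)
    a = _square_wave(n, period, half)
    b = _square_wave(n, period, half, lag=lag)
    return FrameSequence(spec.frame_rate, np.column_stack([a, b]))


def build_alternation_schedule(spec: ScheduleSpec) -> FrameSequence:
    """A on while B off and vice versa; no frame has both components on."""
    if spec.mode not in (Mode.ALTERNATION, Mode.COMPONENT_FIELD):
        raise ValueError(f"spec.mode must be alternation, got {spec.mode}")
    half = half_period_frames(spec.base_frequency, spec.frame_rate)
    period = 2 * half
    n = _n_frames(spec)
    a = _square_wave(n, period, half)
    b = _square_wave(n, period, half, lag=half)
    return FrameSequence(spec.frame_rate, np.column_stack([a, b]))


def build_flicker_schedule(spec: ScheduleSpec) -> FrameSequence:
    """Both components on together, alternating with a blank (50% duty)."""
    if spec.mode is not Mode.SYNCHRONOUS_FLICKER:
        raise ValueError(f"spec.mode must be synchronous_flicker, got {spec.mode}")
    half = half_period_frames(spec.base_frequency, spec.frame_rate)
    n = _n_frames(spec)
    a = _square_wave(n, 2 * half, half)
    return FrameSequence(spec.frame_rate, np.column_stack([a, a.copy()]))


def build_component_field_schedule(
    spec: ScheduleSpec, rng: np.random.Generator | None = None
) -> FrameSequence:
    """The control hemi-field: components in strict alternation.

    If ``rng`` is given, the whole schedule is delayed by a uniformly drawn
    whole-frame lag so the two hemi-fields never alternate in lockstep (the
    temporal phases of the two fields were independently randomized each
    trial in the original procedure).
    """
    base = build_alternation_schedule(
        ScheduleSpec(
            Mode.ALTERNATION,
            spec.base_frequency,
            spec.duration,
            frame_rate=spec.frame_rate,
        )
    )
    if rng is None:
        return base
    half = half_period_frames(spec.base_frequency, spec.frame_rate)
    lag = int(rng.integers(0, 2 * half))
    return FrameSequence(base.frame_rate, np.roll(base.states, lag, axis=0))


_BUILDERS = {
    Mode.PHASE_OFFSET: build_phase_offset_schedule,
    Mode.ALTERNATION: build_alternation_schedule,
    Mode.SYNCHRONOUS_FLICKER: build_flicker_schedule,
    Mode.COMPONENT_FIELD: build_component_field_schedule,
}


def build_schedule(spec: ScheduleSpec) -> FrameSequence:
    """Dispatch to the builder for ``spec.mode``."""
    return _BUILDERS[spec.mode](spec)


@dataclass
class ExposureStats:
    """Per-component exposure summary of a schedule, in integer ms."""

    total_ms: tuple[int, int]
    single_exposure_ms: tuple[int, int]
    frame_ms: float = field(default=1000.0 / DEFAULT_FRAME_RATE)


def _max_run(x: np.ndarray) -> int:
    if not x.any():
        return 0
    padded = np.concatenate([[False], x, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[0::2]).max())


def exposure_stats(seq: FrameSequence) -> ExposureStats:
    """Total on-time and longest single exposure per component.

    Both are frame counts converted to the nearest integer millisecond;
    e.g. a 1-frame exposure at 85 Hz reports as 12 ms.
    """
    if seq.n_frames == 0:
        raise ValueError("empty frame sequence")
    fm = seq.frame_ms
    totals = tuple(int(np.round(seq.states[:, i].sum() * fm)) for i in (0, 1))
    singles = tuple(int(np.round(_max_run(seq.states[:, i]) * fm)) for i in (0, 1))
    return ExposureStats(totals, singles, fm)


def common_cycle_duration(
    frequencies: list[float], frame_rate: float = DEFAULT_FRAME_RATE
) -> float:
    """Shortest duration (s) that is a whole number of cycles of every
    schedule built at the given nominal frequencies.

    Exposure equating between the compound and component fields is exact
    over such a window; evaluating the observer model over it removes
    partial-cycle artifacts.
    """
    periods = [2 * half_period_frames(f, frame_rate) for f in frequencies]
    frames = math.lcm(*periods)
    return frames / frame_rate


def timeline_frame(
    compound: FrameSequence, component: FrameSequence
) -> pd.DataFrame:
    """Tabulate two hemi-field schedules for CSV export."""
    if compound.frame_rate != component.frame_rate:
        raise ValueError("schedules must share a frame rate")
    n = min(compound.n_frames, component.n_frames)
    idx = np.arange(n)
    return pd.DataFrame(
        {
            "frame_index": idx,
            "time_ms": np.round(idx * compound.frame_ms, 3),
            "compound_A": compound.a[:n].astype(int),
            "compound_B": compound.b[:n].astype(int),
            "component_A": component.a[:n].astype(int),
            "component_B": component.b[:n].astype(int),
        }
    )
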