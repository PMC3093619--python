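import numpy as np
import pytest

from compadapt import (
    Mode,
    ObserverParams,
    ScheduleSpec,
    StaircaseConfig,
    TrueEffect,
    build_alternation_schedule,
    build_flicker_schedule,
    build_phase_offset_schedule,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plaid_observer():
    return ObserverParams.default_plaid()


@pytest.fixture
def contour_observer():
    return ObserverParams.default_contour()


@pytest.fixture
def plaid_staircase():
    return StaircaseConfig.default_plaid()


def make_offset(freq, offset_deg, duration=4.0, frame_rate=85.0):
    return build_phase_offset_schedule(
        ScheduleSpec(
            Mode.PHASE_OFFSET, freq, duration, phase_offset=offset_deg,
            frame_rate=frame_rate,
        )
    )


def make_alternation(freq, duration=4.0, frame_rate=85.0):
    return build_alternation_schedule(
        ScheduleSpec(Mode.ALTERNATION, freq, duration, frame_rate=frame_rate)
    )


def make_flicker(freq, duration=4.0, frame_rate=85.0):
    return build_flicker_schedule(
        ScheduleSpec(Mode.SYNCHRONOUS_FLICKER, freq, duration, frame_rate=frame_rate)
    )


def fixed_effect(shift, units="db"):
    """A TrueEffect with a directly injected PSE shift (intensity units)."""
    return TrueEffect(pse_shift=shift, raw=float("nan"), units=units)
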