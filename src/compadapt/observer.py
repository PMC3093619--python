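"""A parametric synthetic observer for compound-adaptation experiments.

The observer is a stand-in for a human participant: it maps an adaptation
condition (a pair of compound/component adaptor timelines) to a true shift
of the point of subjective equality (PSE), then answers 2AFC probe trials
stochastically around that shift.  It exists so that every downstream stage
(staircase, psychometric fit, bootstrap) can be exercised and validated
against a known ground truth; it is an invented generative model, not a
measured property of human vision.

The effect model combines two phenomenological mechanisms:

* a *fast* synchrony-sensitive term - proportional to the fraction of
  frames on which both components are on together, gated by a Gaussian
  penalty on the onset lag between the components with scale
  ``fast_tolerance_ms``.  This produces the abrupt collapse of the plaid
  effect with small temporal phase offsets.
* a *slow* integrator term - the cosine similarity of the two components'
  on-signals after causal exponential low-pass filtering with time constant
  ``slow_window_ms``.  This produces gradual decay with phase offset and
  band-pass integration of rapidly alternating components.

Both terms are attenuated by a phenomenological high-frequency roll-off in
the component flicker rate (standing in for the loss of effective adaptor
contrast near flicker fusion).  The condition's effect is the *difference*
of this drive between the compound and the component field, so identical
adaptors give exactly zero - the paradigm's defining null.

Either gain may be set to zero, so single-mechanism and two-mechanism
accounts can both be simulated; the defaults are calibrated to reproduce
the qualitative shape of the published tuning curves (a ~2.6 dB synchronous
plaid effect collapsing abruptly with offset; band-pass alternation tuning
peaking near 8.5-14 Hz for plaids and above 21 Hz for contours; low-pass
flicker tuning for plaids).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import lfilter

from .schedule import FrameSequence

__all__ = [
    "ObserverParams",
    "TrueEffect",
    "true_effect",
    "respond",
    "choice_probability",
    "fast_term",
    "slow_term",
    "flicker_rate_hz",
]

#: Reference probe contrast for plaid experiments (Michelson).
PLAID_REFERENCE_CONTRAST = 0.42
#: Reference probe curvature for contour experiments, degrees of deviation
#: from a straight contour (a 100-deg probe angle).
CONTOUR_REFERENCE_CURVATURE = 80.0


@dataclass(frozen=True)
class ObserverParams:
    """Tunable parameters of the synthetic observer.

    ``units`` selects how gains are expressed and how the raw effect is
    converted to a PSE shift in stimulus intensity units: ``"db"`` (plaid;
    gains in decibels of matching contrast, converted against
    ``reference_intensity``) or ``"degrees"`` (contour; gains already in
    degrees of curvature).

    ``psychometric_slope`` is the dimensionless shape of the observer's
    cumulative-Weibull response function (larger = steeper choice curve);
    ``lapse_rate`` mixes in stimulus-independent guesses; ``side_bias``
    shifts the PSE by a fixed amount toward one hemi-field and must cancel
    in the side-averaged analysis.
    """

    fast_gain: float
    fast_tolerance_ms: float
    slow_gain: float
    slow_window_ms: float
    psychometric_slope: float
    units: str
    reference_intensity: float
    rolloff_hz: float = 28.0
    rolloff_power: float = 4.0
    lapse_rate: float = 0.01
    side_bias: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fast_gain < 0 or self.slow_gain < 0:
            raise ValueError("gains must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise ValueError("lapse_rate must lie in [0, 0.05]")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be positive")
        if self.units not in ("db", "degrees"):
            raise ValueError("units must be 'db' or 'degrees'")
        if self.reference_intensity <= 0:
            raise ValueError("reference_intensity must be positive")

    @classmethod
    def default_plaid(cls, **overrides) -> "ObserverParams":
        """Plaid observer: a dominant fast mechanism plus a weak slow one,
        yielding ~2.6 dB for the synchronous condition."""
        base = dict(
            fast_gain=2.0,
            fast_tolerance_ms=50.0,
            slow_gain=0.7,
            slow_window_ms=110.0,
            rolloff_hz=28.0,
            rolloff_power=4.0,
            psychometric_slope=10.0,
            units="db",
            reference_intensity=PLAID_REFERENCE_CONTRAST,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def default_contour(cls, **overrides) -> "ObserverParams":
        """Contour observer: a single coarse integrator (no fast term),
        yielding a few degrees of curvature aftereffect."""
        base = dict(
            fast_gain=0.0,
            fast_tolerance_ms=50.0,
            slow_gain=4.3,
            slow_window_ms=35.0,
            rolloff_hz=70.0,
            rolloff_power=4.0,
            psychometric_slope=18.0,
            units="degrees",
            reference_intensity=CONTOUR_REFERENCE_CURVATURE,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrueEffect:
    """Ground-truth compound-adaptation effect for one condition.

    ``pse_shift`` is in stimulus intensity units (Michelson contrast for
    plaids, degrees of curvature for contours); ``raw`` is the same effect
    in the observer's gain units (dB or degrees).  Zero whenever the
    compound and component schedules are identical.
    """

    pse_shift: float
    raw: float
    units: str
    condition: str = ""


def _onsets(x: np.ndarray) -> np.ndarray:
    return np.flatnonzero(x & ~np.roll(x, 1))


def _onset_lag_ms(seq: FrameSequence) -> float:
    """Median circular distance (ms) from each A onset to the nearest B onset."""
    on_a, on_b = _onsets(seq.a), _onsets(seq.b)
    if len(on_a) == 0 or len(on_b) == 0:
        return np.inf
    n = seq.n_frames
    d = np.abs(on_a[:, None] - on_b[None, :])
    d = np.minimum(d, n - d).min(axis=1)
    return float(np.median(d)) * seq.frame_ms


def fast_term(seq: FrameSequence, tolerance_ms: float) -> float:
    """Synchrony drive in [0, 1]: joint-on fraction gated by onset lag."""
    n_a, n_b = int(seq.a.sum()), int(seq.b.sum())
    if min(n_a, n_b) == 0:
        return 0.0
    overlap = int((seq.a & seq.b).sum()) / min(n_a, n_b)
    lag = _onset_lag_ms(seq)
    if not np.isfinite(lag):
        return 0.0
    return overlap * float(np.exp(-((lag / tolerance_ms) ** 2)))


def _lowpass(x: np.ndarray, tau_ms: float, frame_ms: float) -> np.ndarray:
    a = np.exp(-frame_ms / tau_ms)
    return lfilter([1.0 - a], [1.0, -a], x.astype(float))


def slow_term(seq: FrameSequence, window_ms: float) -> float:
    """Coarse-integrator drive in [0, 1]: cosine similarity of the two
    low-pass-filtered on-signals."""
    fa = _lowpass(seq.a, window_ms, seq.frame_ms)
    fb = _lowpass(seq.b, window_ms, seq.frame_ms)
    na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(np.clip(fa @ fb / (na * nb), 0.0, 1.0))


def flicker_rate_hz(seq: FrameSequence) -> float:
    """Mean component on/off cycle rate, from onset counting."""
    n_on = (len(_onsets(seq.a)) + len(_onsets(seq.b))) / 2.0
    return n_on / seq.duration_s


def _drive(seq: FrameSequence, p: ObserverParams) -> float:
    atten = 1.0 / (1.0 + (flicker_rate_hz(seq) / p.rolloff_hz) ** p.rolloff_power)
    return atten * (
        p.fast_gain * fast_term(seq, p.fast_tolerance_ms)
        + p.slow_gain * slow_term(seq, p.slow_window_ms)
    )


def raw_to_shift(raw: float, params: ObserverParams) -> float:
    """Convert an effect in gain units to a PSE shift in intensity units."""
    if params.units == "db":
        return params.reference_intensity * (10.0 ** (raw / 20.0) - 1.0)
    return raw


def true_effect(
    params: ObserverParams,
    compound: FrameSequence,
    component: FrameSequence,
    condition: str = "",
) -> TrueEffect:
    """Ground-truth PSE shift for one compound/component adaptor pair.

    Deterministic in its inputs; returns exactly zero when the two
    schedules are identical frame-for-frame (e.g. a 180-deg phase offset
    versus the alternating component field, or 1 Hz alternation in both
    fields).
    """
    if compound.frame_rate != component.frame_rate:
        raise ValueError("compound and component schedules must share a frame rate")
    if compound.n_frames != component.n_frames:
        raise ValueError("compound and component schedules must share a duration")
    if np.array_equal(compound.states, component.states):
        return TrueEffect(0.0, 0.0, params.units, condition)
    raw = _drive(compound, params) - _drive(component, params)
    return TrueEffect(raw_to_shift(raw, params), raw, params.units, condition)


_LN2 = math.log(2.0)


def choice_probability(
    test_intensity: float,
    reference_intensity: float,
    effect: TrueEffect,
    params: ObserverParams,
    compound_side: str,
) -> float:
    """Probability of judging the compound-side probe more intense.

    The response function is a cumulative Weibull in the probe intensity,
    ``lapse/2 + (1 - lapse) * (1 - exp(-(x / a)^beta))`` with shape
    ``beta = psychometric_slope`` and scale ``a`` positioned so the curve
    crosses 50% exactly at ``reference + pse_shift + bias`` - the same
    family the analysis stage fits.  The side bias adds to the PSE when
    the compound is in the left hemi-field and subtracts when it is in
    the right, so averaging the two sides cancels it.
    """
    if compound_side not in ("left", "right"):
        raise ValueError("compound_side must be 'left' or 'right'")
    bias = params.side_bias if compound_side == "left" else -params.side_bias
    pse = reference_intensity + effect.pse_shift + bias
    if pse <= 0:
        # degenerate limit: a PSE at or below zero on the positive intensity
        # axis means any visible probe exceeds it
        weibull = 1.0 if test_intensity > 0 else 0.0
    elif test_intensity <= 0:
        weibull = 0.0
    else:
        # (x/a)^beta with a = pse / ln2^(1/beta), in log space for stability
        log_t = math.log(_LN2) + params.psychometric_slope * (
            math.log(test_intensity) - math.log(pse)
        )
        weibull = 1.0 - math.exp(-math.exp(min(log_t, 700.0)))
    return params.lapse_rate / 2.0 + (1.0 - params.lapse_rate) * weibull


def respond(
    test_intensity: float,
    reference_intensity: float,
    effect: TrueEffect,
    params: ObserverParams,
    compound_side: str,
    rng: np.random.Generator,
) -> str:
    """One 2AFC judgement: which side appears more intense?

    Bernoulli draw around :func:`choice_probability`; reproducible under a
    seeded generator.
    """
    p_compound = choice_probability(
        test_intensity, reference_intensity, effect, params, compound_side
    )
    return "compound" if rng.random() < p_compound else "component"
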