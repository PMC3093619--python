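"""Adaptive 1-up/1-down staircases and simulated session blocks.

The staircase keeps the test probe near the point of subjective equality:
after a "compound (test) side higher" response the test intensity is
stepped down, otherwise up, with a fixed step and clipping at the intensity
bounds.  Under a stochastic observer this rule converges in distribution to
the 50% point of the psychometric function.

A block is the unit of data collection: several 50-trial staircases with
the compound adaptor in the left hemi-field and the same number with it in
the right (4 + 4 by default, i.e. 200 trials per side), concatenated into
one trial table.  The trial-log CSV written here is the interchange format
consumed by the analysis stage, and externally collected data in the same
layout can be analysed identically.

Session timing (initial adaptation, top-up, ISI, probe durations) is
carried as metadata for the run manifest; it does not alter the simulated
responses, since adaptation build-up and decay within a session are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .observer import ObserverParams, TrueEffect, respond

__all__ = [
    "StaircaseConfig",
    "SessionTimeline",
    "TRIAL_COLUMNS",
    "run_staircase",
    "run_block",
    "write_trials",
    "read_trials",
]

TRIAL_COLUMNS = [
    "session",
    "condition",
    "compound_side",
    "staircase",
    "trial",
    "intensity",
    "response",
    "seed",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Staircase parameters.

    Step size and start value are design choices (the procedure they mimic
    reported neither): the default start sits 8 steps above the reference so
    the staircase sweeps the psychometric range within 50 trials, and the
    step is fixed throughout (no halving).
    """

    n_trials: int = 50
    reference_intensity: float = 0.42
    step_size: float = 0.02
    start_intensity: float | None = None  # defaults to reference + 8 steps
    intensity_bounds: tuple[float, float] = (0.01, 0.98)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        lo, hi = self.intensity_bounds
        if not lo < hi:
            raise ValueError("intensity_bounds must be an increasing interval")
        if not lo <= self.start() <= hi:
            raise ValueError("start intensity must lie within the bounds")

    def start(self) -> float:
        if self.start_intensity is not None:
            return self.start_intensity
        return self.reference_intensity + 8.0 * self.step_size

    @classmethod
    def default_plaid(cls, **overrides) -> "StaircaseConfig":
        """Contrast staircase: 0.42 reference, 0.02 steps, [0.01, 0.98]."""
        base = dict(
            reference_intensity=0.42, step_size=0.02, intensity_bounds=(0.01, 0.98)
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def default_contour(cls, **overrides) -> "StaircaseConfig":
        """Curvature staircase on the deviation-from-straight coordinate:
        an 80-deg reference (100-deg probe angle), 2-deg steps, bounded to
        +/-40 deg around the reference."""
        base = dict(
            reference_intensity=80.0, step_size=2.0, intensity_bounds=(40.0, 120.0)
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class SessionTimeline:
    """Timing of one adaptation session, seconds/milliseconds (metadata)."""

    initial_adapt_s: float = 30.0
    topup_s: float = 2.0
    isi_ms: float = 200.0
    probe_ms: float = 200.0

    def __post_init__(self) -> None:
        if min(self.initial_adapt_s, self.topup_s, self.isi_ms, self.probe_ms) <= 0:
            raise ValueError("all session durations must be positive")

    @classmethod
    def plaid(cls) -> "SessionTimeline":
        return cls(initial_adapt_s=30.0)

    @classmethod
    def contour(cls) -> "SessionTimeline":
        return cls(initial_adapt_s=60.0)

    def to_dict(self) -> dict:
        return asdict(self)


def run_staircase(
    cfg: StaircaseConfig,
    params: ObserverParams,
    effect: TrueEffect,
    compound_side: str,
    rng: np.random.Generator,
    *,
    session: str = "sim",
    condition: str = "",
    staircase_id: int = 0,
    seed_label: int = 0,
) -> pd.DataFrame:
    """Simulate one staircase; returns exactly ``cfg.n_trials`` trial records.

    The test intensity moves one step against each response ("test side
    higher" -> decrease) and is clipped to the configured bounds.
    """
    lo, hi = cfg.intensity_bounds
    intensity = float(np.clip(cfg.start(), lo, hi))
    rows = []
    for t in range(1, cfg.n_trials + 1):
        choice = respond(
            intensity, cfg.reference_intensity, effect, params, compound_side, rng
        )
        rows.append(
            (
                session,
                condition,
                compound_side,
                staircase_id,
                t,
                intensity,
                choice,
                seed_label,
            )
        )
        step = -cfg.step_size if choice == "compound" else cfg.step_size
        intensity = float(np.clip(intensity + step, lo, hi))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_block(
    condition: str,
    params: ObserverParams,
    effect: TrueEffect,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
    n_staircases_per_side: int = 4,
    *,
    session: str = "sim",
    seed_label: int = 0,
) -> pd.DataFrame:
    """One block: ``n_staircases_per_side`` staircases with the compound
    adaptor on each side of fixation, concatenated with side labels.

    The default (4 per side, 50 trials each) yields 200 trials per side --
    the standard per-condition dataset for the analysis stage.
    """
    if n_staircases_per_side < 1:
        raise ValueError("n_staircases_per_side must be at least 1")
    tables = []
    for side in ("left", "right"):
        for k in range(n_staircases_per_side):
            tables.append(
                run_staircase(
                    cfg,
                    params,
                    effect,
                    side,
                    rng,
                    session=session,
                    condition=condition,
                    staircase_id=k,
                    seed_label=seed_label,
                )
            )
    return pd.concat(tables, ignore_index=True)


def write_trials(trials: pd.DataFrame, path: str) -> None:
    """Write a trial log CSV (the simulation/analysis interchange format)."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path: str) -> pd.DataFrame:
    """Read a trial log CSV, restoring column dtypes."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log is missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS].astype(
        {
            "staircase": int,
            "trial": int,
            "intensity": float,
            "seed": int,
        }
    )
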