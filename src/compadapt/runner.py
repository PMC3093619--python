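"""End-to-end orchestration of the three simulated experiments.

Each experiment sweeps one temporal manipulation of the compound adaptor
against the fixed alternating component field:

* ``exp1`` - temporal phase offsets between the two components
  (plaid: 0/8.5/19/36/72/144 deg of a 2000 ms cycle -> 0/47/106/200/400/800 ms;
  contour: 0/21.5/43/90/180 deg of a ~988 ms cycle -> 0/59/118/247/494 ms).
* ``exp2`` - strict alternation of the components at 1-42.5 Hz.
* ``exp3`` - synchronous flicker of both components at 1-42.5 Hz.

For every condition the runner builds the compound and component schedules
over a whole number of cycles of both, computes the observer's ground-truth
effect, simulates a full staircase block, runs the Weibull/PSE/bootstrap
analysis, and collects one results row.  Everything is deterministic given
the master seed: per-condition RNG streams are spawned from it by a stable
counter, so any single condition can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .observer import ObserverParams, true_effect
from .psychometrics import analyze_trials
from .schedule import (
    DEFAULT_FRAME_RATE,
    Mode,
    ScheduleSpec,
    build_alternation_schedule,
    build_flicker_schedule,
    build_phase_offset_schedule,
    common_cycle_duration,
    half_period_frames,
    phase_offset_to_ms,
)
from .staircase import SessionTimeline, StaircaseConfig, run_block, write_trials

__all__ = [
    "ExperimentConfig",
    "EXP1_PLAID_OFFSETS_DEG",
    "EXP1_CONTOUR_OFFSETS_DEG",
    "FREQUENCY_GRID_HZ",
    "condition_schedules",
    "run_experiment",
    "plot_results",
    "RESULT_COLUMNS",
]

#: Phase-offset grids (degrees of the component cycle).
EXP1_PLAID_OFFSETS_DEG = [0.0, 8.5, 19.0, 36.0, 72.0, 144.0]
EXP1_CONTOUR_OFFSETS_DEG = [0.0, 21.5, 43.0, 90.0, 180.0]
#: Alternation / flicker grid (nominal Hz); seven frequencies, realized
#: values quantized to the 85 Hz refresh.
FREQUENCY_GRID_HZ = [1.0, 2.0, 4.0, 8.5, 14.0, 21.0, 42.5]

#: Component-cycle base frequency of the Experiment-1 adaptors (Hz):
#: plaids cycled at 0.5 Hz, contours at nominal 1 Hz (realized 85/84 Hz).
EXP1_BASE_FREQUENCY = {"plaid": 0.5, "contour": 1.0}
#: The component field alternates at 1 Hz everywhere except Exp-1 plaids.
COMPONENT_FIELD_FREQUENCY = {"exp1": EXP1_BASE_FREQUENCY, "exp2": 1.0, "exp3": 1.0}

RESULT_COLUMNS = [
    "experiment",
    "aftereffect",
    "condition",
    "offset_deg",
    "offset_ms",
    "frequency_hz",
    "true_shift",
    "true_raw",
    "pse_left",
    "pse_right",
    "pse_mean",
    "shift",
    "db",
    "ci_lo",
    "ci_hi",
    "n_trials",
    "n_failed_resamples",
    "ci_unreliable",
    "seed",
]


@dataclass
class ExperimentConfig:
    """Complete description of one simulated experiment run."""

    experiment: str
    aftereffect: str
    conditions: list[float]
    observer: ObserverParams
    staircase: StaircaseConfig
    timeline: SessionTimeline
    n_staircases_per_side: int = 4
    n_bootstrap: int = 500
    seed: int = 0
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2", "exp3"):
            raise ValueError("experiment must be exp1, exp2 or exp3")
        if self.aftereffect not in ("plaid", "contour"):
            raise ValueError("aftereffect must be plaid or contour")

    @classmethod
    def default(
        cls,
        experiment: str,
        aftereffect: str,
        seed: int = 0,
        n_bootstrap: int = 500,
        **overrides,
    ) -> "ExperimentConfig":
        """The standard condition grid and defaults for one experiment."""
        if experiment == "exp1":
            conditions = list(
                EXP1_PLAID_OFFSETS_DEG
                if aftereffect == "plaid"
                else EXP1_CONTOUR_OFFSETS_DEG
            )
        else:
            conditions = list(FREQUENCY_GRID_HZ)
        observer = (
            ObserverParams.default_plaid()
            if aftereffect == "plaid"
            else ObserverParams.default_contour()
        )
        staircase = (
            StaircaseConfig.default_plaid()
            if aftereffect == "plaid"
            else StaircaseConfig.default_contour()
        )
        timeline = (
            SessionTimeline.plaid() if aftereffect == "plaid" else SessionTimeline.contour()
        )
        base = dict(
            experiment=experiment,
            aftereffect=aftereffect,
            conditions=conditions,
            observer=observer,
            staircase=staircase,
            timeline=timeline,
            seed=seed,
            n_bootstrap=n_bootstrap,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def units(self) -> str:
        return "contrast" if self.aftereffect == "plaid" else "degrees"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = [float(c) for c in d["conditions"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["observer"] = ObserverParams(**d["observer"])
        sc = dict(d["staircase"])
        sc["intensity_bounds"] = tuple(sc["intensity_bounds"])
        d["staircase"] = StaircaseConfig(**sc)
        d["timeline"] = SessionTimeline(**d["timeline"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _component_frequency(cfg: ExperimentConfig) -> float:
    spec = COMPONENT_FIELD_FREQUENCY[cfg.experiment]
    return spec[cfg.aftereffect] if isinstance(spec, dict) else spec


def condition_schedules(cfg: ExperimentConfig, value: float):
    """Build the compound and component schedules for one condition value.

    Returns ``(compound, component, descriptor)`` where the descriptor maps
    the condition onto the printed units (degrees and frame-quantized ms
    for phase offsets, Hz for frequencies).  Both schedules span the
    shortest whole number of cycles common to the two fields, over which
    exposure is equated exactly.
    """
    comp_freq = _component_frequency(cfg)
    if cfg.experiment == "exp1":
        base = EXP1_BASE_FREQUENCY[cfg.aftereffect]
        duration = common_cycle_duration([base, comp_freq], cfg.frame_rate)
        compound = build_phase_offset_schedule(
            ScheduleSpec(
                Mode.PHASE_OFFSET,
                base,
                duration,
                phase_offset=value,
                frame_rate=cfg.frame_rate,
            )
        )
        cycle_ms = 2 * half_period_frames(base, cfg.frame_rate) * 1000.0 / cfg.frame_rate
        descriptor = {
            "condition": f"offset_{value:g}deg",
            "offset_deg": value,
            "offset_ms": phase_offset_to_ms(value, cycle_ms, cfg.frame_rate),
            "frequency_hz": base,
        }
    else:
        duration = common_cycle_duration([value, comp_freq], cfg.frame_rate)
        builder = (
            build_alternation_schedule
            if cfg.experiment == "exp2"
            else build_flicker_schedule
        )
        mode = Mode.ALTERNATION if cfg.experiment == "exp2" else Mode.SYNCHRONOUS_FLICKER
        compound = builder(
            ScheduleSpec(mode, value, duration, frame_rate=cfg.frame_rate)
        )
        descriptor = {
            "condition": f"freq_{value:g}Hz",
            "offset_deg": math.nan,
            "offset_ms": math.nan,
            "frequency_hz": value,
        }
    component = build_alternation_schedule(
        ScheduleSpec(Mode.ALTERNATION, comp_freq, duration, frame_rate=cfg.frame_rate)
    )
    return compound, component, descriptor


def run_experiment(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Simulate and analyse every condition of one experiment.

    Per-condition seeds are spawned from the master seed by a stable
    counter.  If ``out_dir`` is given, the results CSV, per-condition trial
    logs, and a YAML run manifest are written there.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(len(cfg.conditions))
    rows = []
    trial_logs = {}
    for value, child in zip(cfg.conditions, children):
        compound, component, descriptor = condition_schedules(cfg, value)
        effect = true_effect(
            cfg.observer, compound, component, condition=descriptor["condition"]
        )
        sim_rng, boot_rng = (np.random.default_rng(s) for s in child.spawn(2))
        seed_label = int(child.generate_state(1)[0] % 2**31)
        trials = run_block(
            descriptor["condition"],
            cfg.observer,
            effect,
            cfg.staircase,
            sim_rng,
            cfg.n_staircases_per_side,
            session=f"{cfg.experiment}_{cfg.aftereffect}",
            seed_label=seed_label,
        )
        trial_logs[descriptor["condition"]] = trials
        row = {
            "experiment": cfg.experiment,
            "aftereffect": cfg.aftereffect,
            **descriptor,
            "true_shift": effect.pse_shift,
            "true_raw": effect.raw,
            "seed": seed_label,
        }
        try:
            row.update(
                analyze_trials(
                    trials,
                    cfg.staircase.reference_intensity,
                    cfg.units,
                    n_resamples=cfg.n_bootstrap,
                    rng=boot_rng,
                )
            )
        except ValueError as exc:  # record the failure, continue the sweep
            row["error"] = str(exc)
        rows.append(row)
    results = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in results.columns:
            results[col] = math.nan
    results = results[
        RESULT_COLUMNS + [c for c in results.columns if c not in RESULT_COLUMNS]
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{cfg.experiment}_{cfg.aftereffect}"
        results.to_csv(out / f"{stem}_results.csv", index=False)
        for name, log in trial_logs.items():
            write_trials(log, out / f"{stem}_{name}_trials.csv")
        manifest = {
            "package_version": __version__,
            "config": cfg.to_dict(),
            "condition_seeds": {
                r["condition"]: int(r["seed"]) for r in rows
            },
        }
        (out / f"{stem}_manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=False)
        )
    return results


def _effect_series(results: pd.DataFrame):
    """Effect values and CI bounds on the display scale (dB for plaids,
    degrees for contours)."""
    if (results["aftereffect"] == "plaid").all():
        ref = 0.42
        to_disp = lambda s: 20.0 * np.log10((ref + s) / ref)  # noqa: E731
        label = "compound adaptation (dB)"
        y = to_disp(results["shift"])
        lo = to_disp(results["ci_lo"])
        hi = to_disp(results["ci_hi"])
    else:
        label = "compound adaptation (deg)"
        y, lo, hi = results["shift"], results["ci_lo"], results["ci_hi"]
    return y, lo, hi, label


def plot_results(results: pd.DataFrame, path: str | Path) -> None:
    """Effect-versus-condition figure with 95% CI error bars.

    The zero line marks veridical equality.  Conditions with a missing CI
    are drawn without error bars.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(results) == 0:
        raise ValueError("results table is empty")
    exp = results["experiment"].iloc[0]
    if exp == "exp1":
        x = results["offset_ms"]
        xlabel = "temporal phase offset (ms)"
    else:
        x = results["frequency_hz"]
        xlabel = (
            "alternation frequency (Hz)" if exp == "exp2" else "flicker frequency (Hz)"
        )
    y, lo, hi, ylabel = _effect_series(results)
    x, y, lo, hi = (np.asarray(v, dtype=float) for v in (x, y, lo, hi))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    has_ci = np.isfinite(lo) & np.isfinite(hi)
    ax.errorbar(
        x[has_ci],
        y[has_ci],
        yerr=[y[has_ci] - lo[has_ci], hi[has_ci] - y[has_ci]],
        fmt="o-",
        capsize=3,
    )
    if (~has_ci).any():
        ax.plot(x[~has_ci], y[~has_ci], "o", color="gray")
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    if exp != "exp1":
        ax.set_xscale("log")
        ax.set_xticks(list(results["frequency_hz"]))
        ax.set_xticklabels([f"{v:g}" for v in results["frequency_hz"]])
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"{exp} / {results['aftereffect'].iloc[0]}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
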