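"""Analyse a 2AFC trial log (simulated here; external CSVs work the same).

Demonstrates the analysis chain in isolation: inject a known PSE shift
into the synthetic observer, simulate a standard block (200 trials per
side), and recover the shift with side-averaged Weibull PSEs and a
within-subject bootstrap CI.
"""

import numpy as np

from compadapt import (
    ObserverParams,
    StaircaseConfig,
    TrueEffect,
    analyze_trials,
    read_trials,
    run_block,
    write_trials,
)

true_shift = 0.08  # contrast units: the observer needs 0.08 more contrast
observer = ObserverParams.default_plaid(side_bias=0.03)  # biased on purpose
staircase = StaircaseConfig.default_plaid()
effect = TrueEffect(pse_shift=true_shift, raw=float("nan"), units="db")

trials = run_block("demo", observer, effect, staircase,
                   np.random.default_rng(7))
write_trials(trials, "demo_trials.csv")
trials = read_trials("demo_trials.csv")  # the CSV round-trip is lossless

row = analyze_trials(trials, reference=0.42, units="contrast",
                     n_resamples=500, rng=np.random.default_rng(8))
print(f"true shift          : {true_shift:.3f} (contrast)")
print(f"per-side PSEs       : left {row['pse_left']:.3f}, "
      f"right {row['pse_right']:.3f} (split by the 0.03 side bias)")
print(f"side-averaged shift : {row['shift']:.3f} "
      f"[{row['ci_lo']:.3f}, {row['ci_hi']:.3f}] 95% CI")
print(f"in decibels         : {row['db']:.2f} dB")
print("The left/right PSEs differ by ~2x the bias, but their average")
print("recovers the true shift - the reason both hemi-fields are measured.")
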