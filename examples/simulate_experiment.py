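"""Simulate one full experiment and recover the adaptation-effect curve.

Runs the phase-offset experiment for the plaid aftereffect end to end:
per condition, build the compound/component schedules, derive the
observer's true PSE shift, simulate a block of eight 50-trial staircases
(four per hemi-field), fit Weibull psychometric functions per side,
average the PSEs, and bootstrap a 95% confidence interval.
Takes ~10 s at 500 bootstrap resamples.
"""

from compadapt import ExperimentConfig, plot_results, run_experiment

cfg = ExperimentConfig.default("exp1", "plaid", seed=42, n_bootstrap=500)
results = run_experiment(cfg, out_dir="runs")
plot_results(results, "runs/exp1_plaid.png")

cols = ["condition", "offset_ms", "true_raw", "db", "ci_lo", "ci_hi"]
print(results[cols].to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"))
print()
print("db: recovered compound-adaptation effect, 20*log10(C_adapt/0.42);")
print("true_raw is the observer's ground truth in dB - the synchronous")
print("condition sits near 2.6 dB and collapses once the components are")
print("offset in time; ci_lo/ci_hi bound the PSE shift (contrast units).")
print("Outputs in runs/: results CSV, trial logs, manifest, figure.")
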