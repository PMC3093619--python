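# compadapt

Simulated **compound-adaptation** psychophysics: a library for generating
plaid and chevron-contour stimuli, building frame-exact adaptor timelines,
running simulated two-alternative forced-choice (2AFC) staircase sessions
against a configurable synthetic observer, and recovering adaptation-effect
magnitudes with Weibull psychometric fits, side-averaged PSEs, decibel
conversion and within-subject bootstrap confidence intervals.

## The paradigm

Compound adaptation asks whether the visual system has mechanisms selective
for *conjunctions* of features. One hemi-field adapts to a compound stimulus
— two superimposed gratings forming a plaid, or two abutting gratings forming
a V-shaped contour — while the other adapts to the same two gratings
presented in alternation. Per-component exposure is equated between the
fields, so any component-level aftereffect (contrast adaptation, tilt
aftereffect) is matched on both sides. Test probes are then compared across
the fields and the **point of subjective equality (PSE)** — the probe
intensity at which the observer chooses either side with probability ½ — is
measured. A PSE shifted away from veridical equality is evidence of
adaptation to the compound *as a whole*. Varying the temporal structure of
the compound adaptor (phase offsets between the components, alternation rate,
flicker rate) maps the temporal tuning of the binding mechanism.

The analysis chain fits a Weibull function

    P(choose compound) = λ/2 + (1 − λ)·(1 − exp(−(x/α)^β))

to the pooled responses per side by binomial maximum likelihood, takes the
50% crossing `α·(ln 2)^{1/β}` as the PSE, averages the left- and
right-compound PSEs to cancel side bias, and reports contrast effects in
decibels, `dB = 20·log₁₀(C_adapt/C)` with C the 0.42 reference contrast.
95% CIs come from resampling trials with replacement per side and refitting
(percentile method).

Because no human data are involved, a **synthetic observer** closes the
loop: a two-mechanism effect model (a fast synchrony detector with ~50 ms
tolerance and a coarse ~100 ms integrator, both attenuated near flicker
fusion) maps each adaptation condition to a ground-truth PSE shift, and
responses are binomial around a logistic psychometric function with lapses
and an optional hemi-field bias. Every downstream stage is thereby testable
against a known truth. See `docs/methods.md` for the full model.

## Worked example

```bash
python examples/simulate_experiment.py
```

simulates the phase-offset experiment for the plaid aftereffect (eight
50-trial staircases per condition, 500 bootstrap resamples) and prints:

```
    condition  offset_ms  true_raw    db  ci_lo  ci_hi
  offset_0deg          0     2.656 2.650  0.141  0.158
offset_8.5deg         47     1.435 1.333  0.061  0.078
 offset_19deg        106     0.646 0.601  0.023  0.037
 offset_36deg        200     0.571 0.623  0.024  0.037
 offset_72deg        400     0.425 0.389  0.012  0.025
offset_144deg        800     0.120 0.127 -0.003  0.014
```

Reading the table: `offset_ms` is the frame-quantized lag between the two
plaid components (9 frames at 85 Hz for the 19° condition → 106 ms);
`true_raw` is the observer's ground-truth compound-adaptation effect in dB;
`db` is what the full staircase → Weibull → side-averaged-PSE chain
recovered; `ci_lo`/`ci_hi` bound the PSE shift in contrast units. The
synchronous condition shows a ~2.6 dB effect that collapses abruptly once
the components are offset in time — the signature of a synchrony-sensitive
binding mechanism — while a small residual effect decays slowly toward the
anti-phase null. (Exact digits vary with the seed; the run above used
`seed=42`.)

Other examples: `render_stimuli.py` (plaid/contour PNGs and their 8°/10°×5°
envelope extents), `build_schedules.py` (timeline construction and the
exposure-equating control), `observer_tuning.py` (ground-truth tuning curves
of all three experiments), `analyze_trial_log.py` (the analysis chain on a
trial-log CSV, including side-bias cancellation).

A thin CLI wraps the same functionality:

```bash
compadapt render --kind plaid --out plaid.png
compadapt schedule --mode alternation --freq 8.5 --duration 2 --out timeline.csv
compadapt simulate --experiment exp1 --aftereffect plaid --seed 42 --out runs/
compadapt analyze runs/exp1_plaid_offset_0deg_trials.csv \
    --reference 0.42 --units contrast
```

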