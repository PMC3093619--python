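# Methods

`compadapt` simulates the *compound adaptation* paradigm of visual
psychophysics end to end. The paradigm measures adaptation to a conjunction
stimulus (a plaid, or a chevron-like contour) over and above adaptation to its
component gratings: one hemi-field adapts to the compound, the other to the
two components presented in alternation, with per-component exposure equated
between the fields. Any *difference* in the aftereffect between the two
hemi-fields — measured as a shift of the point of subjective equality (PSE)
between matched test probes — is then attributable to adaptation of
conjunction-selective mechanisms. This note records the models, conventions
and numerical choices the package commits to, and what its tests do and do
not establish.

## Stimuli

Gratings are parametrised by orientation (degrees clockwise from vertical),
spatial frequency (c/deg), spatial phase and Michelson contrast (≤ 0.98, the
display ceiling). Plaids are the pointwise sum of two gratings (default:
±45°, 0.8 c/deg, 0.49 contrast each) under an isotropic Gaussian envelope
(σ = 1.33°, hence an 8° diameter at the 1%-of-peak cutoff, from the closed
form `2σ√(2 ln(1/cutoff))`). Contours abut two oblique gratings (1.1 c/deg,
0.98 contrast) along a vertical hard edge under an anisotropic envelope
(σ_h = 1.67°, σ_v = 0.83° → 10° × 5° at 1%).

The mapping from a contour's apex angle θ to its component orientations is a
package convention, since "oblique, V-shaped contour of θ" does not fix the
absolute orientations: components are tilted ±(180° − θ)/2 from horizontal,
mirrored about the vertical midline, so the chevron opens sideways and
θ = 180° degenerates to a straight horizontal contour. Rendering uses
pixel-centre sampling at 32 px/deg (≥ 25 samples per cycle at 1.1 c/deg) on a
grid with no sample on the midline, which makes mirror-symmetry properties
exact in floating point. Rendered images are for export and inspection only;
the simulation operates on the parametric specs.

## Temporal schedules

Adaptor timelines are boolean per-frame states of the two components at the
85 Hz monitor refresh. All cycles are square waves with 50% duty; the
half-period is quantized to the nearest whole frame (ties to even), and the
realized period is twice that. Consequences worth noting:

- a nominal 1 Hz cycle realizes a 42-frame (494 ms) half-period, i.e.
  "just over 1 Hz" — which is precisely why the printed condition timings
  (47/106/200/400/800 ms for the 0.5 Hz plaid cycle, 59/118/247/494 ms for
  the ~1 Hz contour cycle) come out as they do when degree-valued phase
  offsets are converted through `phase_offset_to_ms`;
- the seven-point frequency grid 1/2/4/8.5/14/21/42.5 Hz realizes half
  periods of 42/21/11/5/3/2/1 frames;
- a single exposure at 42.5 Hz is exactly one 12 ms frame. The often-quoted
  "500 ms at 1 Hz" is the nominal value; the frame-exact number this package
  reports is 494 ms, consistent with the realized hardware timing.

A 180° phase offset and strict alternation produce identical frame
sequences, which is the paradigm's built-in null: at that point the compound
and component adaptors are the same stimulus.

Exposure equating (equal per-component total on-time in the two fields) is
exact over any whole number of cycles of both fields. Over an arbitrary
window the partial-cycle discrepancy can reach half a period, so schedule
pairs for the effect model and the equating checks are built over the least
common multiple of the two fields' periods (`common_cycle_duration`; at most
924 frames ≈ 10.9 s on the default grids). The component field may
additionally be rolled by a uniformly drawn whole-frame lag, mirroring the
per-trial randomisation of the two fields' relative phase; the canonical
(unlagged) schedules are used when computing ground-truth effects so the
null remains exact.

## The synthetic observer

No generative observer exists in the literature for this paradigm — the
published work measures effects, it does not model their production — so the
observer here is an explicit invention, built to be *calibratable* to the
qualitative shapes of the published tuning curves and to expose a known
ground truth to the analysis chain. The drive an adaptor schedule exerts is

    g(S) = r(f) · [ g_fast · sync(S) + g_slow · integ(S) ]

with three ingredients:

- **Fast synchrony term** `sync(S)`: the fraction of on-frames on which both
  components are on together (normalised by the smaller component's
  on-count), multiplied by a Gaussian gate `exp(−(lag/τ_fast)²)` on the
  median onset lag between the components. Default τ_fast = 50 ms, the scale
  at which a ~20 Hz-resolution synchrony mechanism collapses.
- **Slow integrator term** `integ(S)`: the cosine similarity of the two
  components' on-signals after causal exponential low-pass filtering with
  time constant τ_slow. Cosine similarity, not Pearson correlation, is
  deliberate: filtered anti-phase square waves converge to a shared DC level
  whose agreement is exactly what an integrator should credit, whereas
  mean-removal would leave only the residual anti-phase ripple and drive the
  correlation to −1 at high rates. Defaults: τ_slow = 110 ms (plaid),
  35 ms (contour).
- **High-frequency roll-off** `r(f) = 1/(1 + (f/f_c)^4)` on the component
  flicker rate f (onsets per second), a phenomenological stand-in for the
  loss of effective adaptor contrast near flicker fusion. Defaults
  f_c = 28 Hz (plaid; contrast adaptation is strongly contrast-dependent)
  and 70 Hz (contour; the curvature aftereffect is not).

The condition's true effect is `g(compound) − g(component)`, so identical
adaptors give exactly zero. Gains are expressed in decibels for plaids
(converted to a contrast shift against the 0.42 reference via
`C·(10^(dB/20) − 1)`) and degrees of curvature for contours. Defaults
(plaid: g_fast = 2.0 dB, g_slow = 0.7 dB; contour: g_fast = 0, g_slow =
4.3°) put the synchronous plaid condition near 2.6 dB, the plaid alternation
peak at 14 Hz, and the contour alternation peak at 21 Hz — the qualitative
published pattern. Setting either gain to zero simulates a single-mechanism
observer; the package takes no position on which account is true.

Responses are binomial around a cumulative-Weibull response function,
`λ/2 + (1−λ)·(1 − exp(−(x/a)^β))`, with dimensionless shape
`β = psychometric_slope` (defaults 10 for plaid, 18 for contour — chosen so
one staircase step moves the choice probability by roughly 15 percentage
points near the PSE), lapse λ = 0.01, and the scale `a` positioned so the
50% crossing sits exactly at PSE = reference + true shift ± side bias (sign
set by which hemi-field holds the compound). Using the same response family
the analysis fits is deliberate: it makes the Weibull analysis correctly
specified for the synthetic observer, so parameter-recovery tests measure
the chain's estimation error rather than a model-mismatch bias. (An earlier
logistic variant left a systematic ≈0.8° overshoot on the curvature axis —
the 50% point of the best-fitting Weibull does not coincide with a logistic's
on an axis far from zero.) What passing recovery tests can show is therefore
calibration under a well-specified observer; robustness to response-function
mismatch is a separate question the least-squares/logistic cross-check only
touches.

## Staircases and sessions

A 1-up/1-down staircase of 50 trials adjusts the test-probe intensity
against each response with a fixed step, clipped to bounds; this rule
converges on the 50% point (the PSE). Step size and start value are package
choices (the original procedure reported neither): 0.02 contrast / 2° steps,
start 8 steps above the reference (0.42 contrast; 100° probe angle = 80° on
the curvature coordinate), bounds [0.01, 0.98] contrast / ±40° curvature.
A block is 4 staircases per compound side (200 trials per side). Contour
probe angles are mapped to the positive curvature coordinate `180° − angle`
(degrees of deviation from straight), an invertible relabelling that keeps
the Weibull's positive domain. Session timing (30 s/60 s initial adaptation,
2 s top-ups, 200 ms ISI and probes) is carried as manifest metadata only:
adaptation build-up and decay within a session are not modelled, so the
timeline does not influence simulated responses.

## Analysis chain

Per side, responses are pooled per intensity level and a Weibull
psychometric function `λ/2 + (1−λ)(1 − exp(−(x/α)^β))` is fit by binomial
maximum likelihood over (log α, log β) with an analytic gradient (L-BFGS-B;
α bounded to the data range ± one span, β ∈ [0.2, 80]; lapse fixed at 0.01 —
estimating it from 200 trials is unstable). Likelihood weighting means
levels visited often (near the PSE, by construction of the staircase) count
more. A least-squares-on-proportions fit is kept as a cross-check option.
The PSE is the 50% crossing, which with the symmetric lapse term is
`α·(ln 2)^{1/β}` in closed form. The left- and right-compound PSEs are
averaged, cancelling any fixed side bias; effects are the shift of that
average from veridical equality, with the decibel form
`20·log₁₀(C_adapt/C)` attached for contrast data.

Confidence intervals are within-subject bootstrap: each resample redraws
every side's trials with replacement at the original count, refits both
functions, and averages the PSE pair; the 95% CI is the 2.5/97.5 percentile
band (5000 resamples at the published scale; 500 in the default quick path,
which simulation shows is already percentile-stable at these trial counts).
Resamples with a failed fit on either side are dropped and counted, and more
than 20% failures flags the CI unreliable — the drop-and-count policy is a
package choice, as is trial-level (rather than staircase-level) resampling,
the most literal reading of "200 trials per side". Trials are canonically
sorted before resampling so every estimate is invariant to the row order of
the input table. Per-condition CIs are reported without multiple-testing
correction, matching the original analysis.

## Orchestration and reproducibility

`run_experiment` sweeps a condition grid (phase offsets 0–144°/0–180°;
frequencies 1–42.5 Hz — the seven values named in the source text, an
inference since the intermediate values are not all printed), builds
schedules, computes the ground truth, simulates a block and analyses it.
Per-condition RNG streams are spawned from the master seed with
`numpy.random.SeedSequence` by a stable counter, so runs are bitwise
reproducible and any condition can be regenerated in isolation. Outputs are
a results CSV, per-condition trial logs, a YAML manifest (config, seeds,
package version) and tuning-curve figures with the zero line at veridical
equality.

## What the tests show, and what they do not

The synthetic observer emulates: sigmoidal 2AFC choice with lapses, a
condition-dependent PSE shift, hemi-field bias, and staircase-driven
sampling concentrated near the PSE. It does **not** emulate: adaptation
dynamics within or across sessions, sequential dependencies between trials,
learning or fatigue drifts, criterion shifts, or inhomogeneous lapse
behaviour. Passing parameter-recovery and coverage tests therefore
establishes that the analysis chain is correct and well calibrated *for
binomially behaving observers*, not that human data would be recovered with
the same fidelity. The published human effect magnitudes are measurements,
not model predictions; they are used only to calibrate default observer
gains and are never test oracles.

Reduced problem sizes used in the validation suite (chosen to keep the
default runs at desk scale): 500 bootstrap resamples instead of 5000;
50 replicates for the anti-phase null; 20 seeds per injected shift for
recovery; 200 replicates at 100 trials per side for CI coverage. At these
sizes the percentile CIs are stable to well under one staircase step.

## Known limitations

- The fast/slow functional forms are phenomenological; only their
  qualitative tuning (abrupt phase sensitivity, band-pass alternation
  integration, low-pass flicker dependence) is meaningful, not their
  parametric details.
- The high-frequency roll-off folds perceived-contrast loss near flicker
  fusion into a single attenuation factor on the adaptor drive.
- The staircase uses fixed linear steps; logarithmic or halving rules would
  change the sampling density but are not implemented beyond configuration
  of the fixed step.
- The contour reference probe angle is genuinely underdetermined (the
  adaptor apex is 140° while veridical probe equality sits at 100°); the
  default follows the latter and is configurable.
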