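"""Ground-truth temporal tuning curves of the default synthetic observers.

Evaluates the two-mechanism observer model (fast synchrony detector +
coarse integrator) over the condition grids of all three experiments,
without any trial simulation: these are the PSE shifts the stochastic
pipeline is asked to recover.
"""

from compadapt import ExperimentConfig, condition_schedules, true_effect

for experiment in ("exp1", "exp2", "exp3"):
    for aftereffect in ("plaid", "contour"):
        cfg = ExperimentConfig.default(experiment, aftereffect)
        unit = "dB" if aftereffect == "plaid" else "deg"
        parts = []
        for value in cfg.conditions:
            compound, component, desc = condition_schedules(cfg, value)
            eff = true_effect(cfg.observer, compound, component)
            label = (f"{desc['offset_ms']}ms" if experiment == "exp1"
                     else f"{value:g}Hz")
            parts.append(f"{label}:{eff.raw:+.2f}")
        print(f"{experiment}/{aftereffect:8s} ({unit:3s}): " + "  ".join(parts))

print()
print("Reading the curves: the plaid effect collapses abruptly with any")
print("phase offset (fast mechanism), alternating components are integrated")
print("best at intermediate rates (slow mechanism x high-frequency roll-off),")
print("and flicker tuning is low-pass for plaids; the contour effect decays")
print("gradually with offset and peaks at high alternation rates.")
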