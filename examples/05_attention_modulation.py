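"""Compare neutral, spatial, and feature-based attention on one stimulus.

Spatial attention sends the same weak top-down drive into L2/3 and L5 of all
microcircuits; feature-based attention sends it only into the microcircuit
preferring the attended orientation.  The scenario runner builds the network
once, simulates all condition x trial combinations, and computes tuning fits
and per-neuron attention indices (AI = (A-U)/(A+U)).
"""

from laminet import run_scenario
from laminet.experiments import Condition, Scenario, desk_spec

spec = desk_spec(k=0.125, record_ms=500.0)
scenario = Scenario(
    name="attention_demo",
    conditions=(
        Condition("neutral", stimuli=(0.0,)),
        Condition("feature", stimuli=(0.0,), attention_mode="feature",
                  attended_deg=0.0),
    ),
    n_trials=3,
    compute_tuning=True,
    compute_ai=True,
)
bundle = run_scenario(scenario, spec, seed=11)

mean_params = bundle.tuning.groupby(["condition", "layer"])[
    ["baseline_hz", "amplitude_hz", "sigma_deg"]
].mean()
print("mean Gaussian tuning parameters over trials:")
print(mean_params.round(2))
print("\nattention-index summary (readout microcircuit, L2/3+L5):")
print(bundle.ai_summary.round(3).to_string(index=False))
print("\nPositive median AI for the attended microcircuit means attention "
      "shifted per-neuron rates upward relative to the neutral condition.")
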