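"""Signal-detection d' for coarse discrimination under external noise.

The vertical-bar response of the 0-degree microcircuit is compared with the
response of the 90-degree microcircuit (which, by ring symmetry, stands in
for the 0-degree microcircuit's response to a horizontal bar):
d' = (m_v - m_h) / sqrt((s_v^2 + s_h^2)/2).  External noise drives all
non-preferred microcircuits through the bottom-up pathway and erodes the
separation.
"""

from laminet import run_scenario
from laminet.experiments import Condition, Scenario, desk_spec

spec = desk_spec(k=0.125, record_ms=400.0)
conds = tuple(
    Condition("neutral", stimuli=(0.0,), noise_hz=level)
    for level in (2.5, 15.0)
)
scenario = Scenario("dprime_demo", conds, n_trials=6, dprime_comparison_mc=4)
bundle = run_scenario(scenario, spec, seed=21)

cols = ["noise_hz", "layer", "mean_pref_hz", "mean_nonpref_hz", "d_prime"]
print(bundle.dprime[cols].round(2).to_string(index=False))
print("\nHigher noise raises the non-preferred response and shrinks the "
      "separation, so d' falls: discrimination degrades with external noise.")
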