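"""Simulate background-driven spontaneous activity and print layer rates.

Every neuron receives an independent excitatory Poisson background whose
per-population rates are calibrated so the network idles near the model's
physiological spontaneous rates (e.g. L5e ~15 Hz, L6e ~0.6 Hz at reference
scale).  At strongly reduced scale the rates shift somewhat because
downscaling inflates input fluctuations.
"""

import numpy as np

from laminet import build_network, load_model_spec, population_rate, scale_spec
from laminet.config import POPULATIONS
from laminet.engine import attach_background, simulate

spec = scale_spec(load_model_spec(None), 0.125)
net = build_network(spec, seed=1)
bg = attach_background(net, spec)
spk = simulate(net, bg, duration_ms=1200.0, dt_ms=0.1, seed=7, neuron=spec.neuron)
print(f"{spk.gids.size} spikes from {net.n_neurons} neurons (1 s recorded)")
for pop in POPULATIONS:
    gids = np.concatenate([net.pop_gids(mc, pop) for mc in range(8)])
    r = population_rate(spk, gids, (200.0, 1200.0))
    print(f"  {pop:5s} {r:6.2f} Hz")
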