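"""Build a small network and check the wiring against its binomial law.

Each ordered neuron pair is connected independently with the tabulated
probability, so realized in-degrees follow Binomial(N_pre, C).
"""

import numpy as np

from laminet import build_network, load_model_spec, scale_spec, expected_indegree

spec = scale_spec(load_model_spec(None), 0.05)
net = build_network(spec, seed=1)
print(f"built {net.n_neurons} neurons, {net.n_edges} synapses "
      f"(min delay {net.min_delay_ms:.2f} ms)")

# realized mean in-degree of L2/3e from L4e in microcircuit 0
l4e = net.pop_slice(0, "L4e")
l23e = net.pop_slice(0, "L23e")
mask = ((net.pre >= l4e.start) & (net.pre < l4e.stop)
        & (net.post >= l23e.start) & (net.post < l23e.stop))
n_post = l23e.stop - l23e.start
realized = mask.sum() / n_post
expected = expected_indegree(spec.connectivity.prob("L4e", "L23e"),
                             spec.population_size("L4e"))
print(f"L4e->L2/3e mean in-degree: realized {realized:.1f}, expected {expected:.1f}")
print("inhibitory edges are negative:",
      bool((net.weight < 0).any()) and float(net.weight.min()), "pA")
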