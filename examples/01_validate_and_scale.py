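"""Load the reference model parameterization and inspect scaling.

The reference network is eight orientation-selective microcircuits of 19,294
neurons each.  Downscaling by k shrinks every population to round(k*N) and
multiplies recurrent weights by 1/k so the expected summed input per neuron
is unchanged.
"""

from laminet import load_model_spec, scale_spec, expected_indegree
from laminet.config import POPULATIONS

spec = load_model_spec(None)
print(f"reference network: {spec.total_neurons} neurons "
      f"({spec.ring.n} microcircuits x {spec.mc_size})")
for pop in POPULATIONS:
    print(f"  {pop:5s} {spec.population_size(pop):5d}")

k = 0.125
small = scale_spec(spec, k)
print(f"\nscaled by k={k}: {small.total_neurons} neurons, "
      f"recurrent weight factor {small.weight_factor:g}x")

# in-degree x weight is invariant under scaling
c = spec.connectivity.prob("L4e", "L23e")
for s in (spec, small):
    indeg = expected_indegree(c, s.population_size("L4e"))
    w = s.recurrent_weight_pa("e", intra_mc=True)
    print(f"  k={s.scale_k:<6g} L4e->L2/3e in-degree {indeg:7.1f} "
          f"x weight {w:7.1f} pA = {indeg * w:9.1f}")
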