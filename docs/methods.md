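# Methods

`laminet` simulates a patch of early visual cortex as eight
orientation-selective, layered microcircuits that share one receptive field,
and implements the statistics used to quantify how spatial and feature-based
attention reshape orientation tuning. This note records the model, the
parameter choices that were genuinely open, the numerical decisions, and
what the packaged tests do and do not establish.

## Model

**Architecture.** Each microcircuit spans layers 2/3, 4, 5 and 6, each layer
holding an excitatory and an inhibitory pool (reference sizes 5171/1459,
5479/1370, 1213/266, 3599/737; 19,294 neurons per microcircuit, 154,352 in
the full ring). The eight microcircuits prefer orientations 0°, 22.5°, …,
157.5°. Within a microcircuit, every ordered neuron pair is connected
independently with the pathway's tabulated probability (pairwise Bernoulli;
no multapses, no autapses). Across microcircuits, two pathways run inside
L2/3: *lateral inhibition* — L2/3e of one microcircuit onto L2/3i of every
other (p = 0.03) — and *similar-orientation excitation* — L2/3e onto L2/3e
of the two ring-adjacent microcircuits (p = 0.06). "Similar selectivity" is
operationalized as ring distance 1; a config key widens it. The ablated
("modified") model drops the Exc–Exc pathway.

**Neurons and synapses.** Leaky integrate-and-fire neurons with
exponential-current synapses: τ_m = 10 ms, C_m = 250 pF, E_L = V_reset =
−65 mV, θ = −50 mV, absolute refractory period 2 ms, τ_syn = 0.5 ms. The
base excitatory weight is 87.8 pA (PSC amplitude); inhibitory weights are
−g·w with g = 4. All intra-microcircuit weights carry an extra factor 1.6 —
the model family's compensation for its reduced size. Delays are normal
(excitatory 1.5 ± 0.75 ms, inhibitory 0.8 ± 0.4 ms), clipped from below at
one simulation step. These neuron/synapse values are the standard
parameters of the layered-microcircuit lineage this network descends from.

**Inputs.** Three fiber classes, all excitatory Poisson:

- *Background*: each neuron owns an independent bundle (1500–2900 fibers by
  population). Per-population fiber rates are calibrated (below).
- *Stimulus*: an oriented bar is one 225-fiber bundle per microcircuit,
  firing at `20·exp(−Δ²/(2·30°²))` Hz, where Δ is the circular
  (180°-periodic) distance between bar and preferred orientation. The
  falloff family and width are config keys: the published material fixes
  the 20 Hz peak and the qualitative decay but not the functional form; a
  30° width reproduces tuning curves with roughly the published sharpness.
  Fibers project to L4e/L4i/L6e/L6i with probabilities
  0.0983/0.0619/0.0512/0.0196.
- *Attention*: 300-fiber, 5 Hz bundles into L2/3 and L5 (p = 0.13 onto E,
  0.075 onto I). *Spatial* mode drives all eight microcircuits with
  statistically identical, independent bundles; *feature* mode drives only
  the microcircuit preferring the attended orientation.
- *Noise*: external noise reuses the bottom-up pathway (225 fibers,
  Table-6 probabilities) at a flat rate (2.5–15 Hz) into every microcircuit
  except the stimulus-preferring one. The fiber count is not printed for
  noise; it inherits the stimulus value.

**Calibrated parameters.** Two quantities are not printed in the main text
and had to be fixed by calibration; both were frozen before any test was
written and are recorded in `data/defaults.yaml`:

- *Background fiber rates* (per population, 2.5–5.2 Hz): obtained by a
  diffusion-approximation (Siegert-rate, with the usual colored-noise
  threshold shift) solve targeting the model's published spontaneous rates
  (L2/3e ∼3.3, L4e ∼2.4, L5e ∼15, L6e ∼0.6 Hz; inhibitory ∼8/6/9/8 Hz),
  followed by a few damped closed-loop iterations at quarter scale. The
  network is inhibition-stabilized, so per-population feedback control is
  paradoxical and diverges if pushed; the best stable iterate was kept
  (worst deviation ≈ +36 % on L2/3e at k = 0.25).
- *Input-fiber weight* (`synapse.w_input_pa` = 1400 pA, shared by stimulus,
  attention and noise fibers): with the base 87.8 pA weight the 225-fiber
  stimulus depolarizes an L4e neuron by <1 mV and produces no measurable
  tuning. The weight was raised until the model reproduces the published
  phenomenology — peak/trough tuning ratio ≈ 2–3 in L2/3e, suppression of
  non-preferred microcircuits below their spontaneous rate, spatial
  attention raising L2/3+L5 while lowering L4, feature-based attention
  raising the attended and suppressing the orthogonal microcircuit.

**Downscaling.** `scale_spec(spec, k)` shrinks every population to
round(k·N) (round-half-up, floor 1) and multiplies recurrent weights by
(1/k)^e with e = 1 by default, preserving the expected summed input per
neuron. The worked precedent inside the model itself is k = 0.625 → ×1.6.
Mean-preserving compensation inflates input *variance* by 1/k, so
fluctuation-driven rates drift upward as k falls; the exponent is exposed
for users who prefer variance-oriented compensation (e = 0.5). External
fiber counts and weights are never rescaled.

## Simulation engine

Sub-threshold dynamics are linear, so the engine applies the exact
matrix-exponential propagator of (V, I_syn) per step (dt = 0.1 ms default)
rather than Euler stepping; halving dt changes population rates by <2 %.
Spikes are detected on the grid, V is clamped at reset during
refractoriness, and synaptic events travel through a circular delay buffer
with delays rounded to the grid (minimum one step). Poisson inputs are
drawn by inverse transform from per-rate CDF tables truncated where the
survival probability falls below ~1e-12, using an inline xorshift128+
generator seeded per run: identical (network, inputs, duration, dt, seed)
give bit-identical spike trains. A vectorized numpy backend implements the
same update rule with numpy's RNG and serves as an independent cross-check
at the level of firing statistics; no established spiking simulator is part
of the environment, so backend equivalence is checked between these two
implementations.

Trials discard a 200 ms warm-up and analyze 1000 ms of recorded time by
default (both config keys; the published material does not state trial
length). Per scenario, the network and the fiber wiring are built once and
trials vary only the Poisson realization: per-neuron significance tests
across trials require persistent neuron identity, which forces fixed
wiring; a fresh wiring per trial remains available by changing the build
seed.

## Analysis

- *Population rate*: spikes in window / (neurons × window).
- *Tuning fit*: nonlinear least squares of b + a·exp(−(θ−μ)²/(2σ²)) on the
  eight microcircuit rates, orientations re-centered to (−90°, +90°] around
  the stimulus; bounds b ≥ 0, σ ∈ (0°, 90°], μ ∈ [−90°, 90°]; six
  deterministic multi-starts (μ ∈ {−45°, 0°, 45°} × σ ∈ {15°, 30°}), best
  residual wins, ties keep the earlier start.
- *Condition comparisons*: two-sample t-tests per Gaussian parameter across
  trials; exactly-degenerate variance with equal means reports p = 1 by
  convention. Peak locations compare |μ| by two-sided Mann–Whitney U.
- *Attention index*: AI = (A−U)/(A+U) per neuron with A the attended and U
  the neutral trial-mean rate, over L2/3+L5 of the stimulus-preferring
  microcircuit; AI is undefined (excluded) when A+U = 0. Modulation ratio
  (1+AI)/(1−AI). Per-neuron significance is a two-sample t-test across
  trials at α = 0.05 (the published material uses both 0.05 and 0.01 in
  different places; 0.05 is the default, configurable). The excitatory vs
  inhibitory contrast in the proportion of positively modulated neurons is
  a bootstrap over significantly modulated neurons (1000 resamples,
  two-sided tail fraction of the proportion difference).
- *Discriminability*: d′ = (m_v − m_h)/√((σ_v²+σ_h²)/2) over trial-wise
  population rates; the RMS-pooled denominator is the standard
  signal-detection form (a simple-average variant is available). The
  non-preferred response is read, by ring symmetry, from the 90°
  microcircuit (coarse) or the 22.5° microcircuit (fine) in the same
  vertical-bar runs.

## Problem sizes used by the packaged tests and acceptance script

Full-scale runs (154k neurons, ≈2.9·10⁸ synapses, 50 trials) are
overnight-class jobs; the packaged suite instead runs the complete pipeline
at k = 0.125 (19,288 neurons) with 10–20 trials and 400–600 ms recorded per
trial, which one CPU completes in minutes. The acceptance script uses the
same scale. These runs exercise every mechanism at full fidelity but sit at
a different statistical operating point: rates carry the 1/k variance
inflation, trial-to-trial SDs of population rates are small and make d′
estimates noisy at modest trial counts, and quenched per-microcircuit
wiring variability is larger than at reference scale. Directional effects
(attention raising/lowering specific layers, noise eroding d′) are robust
at this scale; printed-value agreement (e.g. spontaneous rates to ±30 %)
is a reference-scale statement.

## Known limitations

- The synthetic conditions model stationary Poisson drive only: no stimulus
  onset/offset transients, no contrast parameterization, no spatially
  separated stimuli, and no plasticity.
- Simple/complex cell distinctions, oscillation/synchrony analyses and
  cross-area coordination are out of scope.
- The two calibrated parameters (background rates, input-fiber weight)
  absorb whatever difference exists between this implementation's operating
  point and the original's unpublished supplement values; conclusions about
  absolute rates therefore carry that uncertainty, while the attention
  contrasts (the model's point) are structural.
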