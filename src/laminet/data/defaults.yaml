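# Reference parameterization of the 8-microcircuit layered attention model.
# Population sizes, connection-probability tables, external-input projection
# probabilities and rates follow the published model; neuron, synapse and
# background parameters are the standard values of the layered-microcircuit
# family of models this network descends from.

ring:
  n_orientations: 8          # preferred orientations 0..157.5 deg, 22.5 deg apart

populations:                 # neurons per layer of one microcircuit
  L23: {e: 5171, i: 1459}
  L4:  {e: 5479, i: 1370}
  L5:  {e: 1213, i: 266}
  L6:  {e: 3599, i: 737}

# Connection probabilities C[post, pre]; rows = target layer, columns = source
# layer, order L2/3, L4, L5, L6.  A postsynaptic neuron receives a synapse from
# each presynaptic neuron independently with probability C.
connectivity:
  ee:                         # excitatory -> excitatory
    - [0.1960, 0.1405, 0.0534, 0.0126]
    - [0.0127, 0.0859, 0.0111, 0.0750]
    - [0.1684, 0.0680, 0.1255, 0.0338]
    - [0.0258, 0.0349, 0.0947, 0.0664]
  ei:                         # excitatory -> inhibitory
    - [0.1669, 0.0601, 0.1250, 0.0070]
    - [0.1144, 0.1809, 0.0055, 0.1750]
    - [0.0722, 0.0346, 0.0937, 0.0142]
    - [0.0603, 0.0056, 0.0459, 0.1089]
  ie:                         # inhibitory -> excitatory
    - [0.2570, 0.1041, 0.0,    0.0]
    - [0.0098, 0.2405, 0.0005, 0.0]
    - [0.1030, 0.0094, 0.6233, 0.0]
    - [0.0109, 0.0275, 0.0326, 0.3728]
  ii:                         # inhibitory -> inhibitory
    - [0.2270, 0.0853, 0.0,    0.0]
    - [0.0048, 0.2644, 0.0,    0.0]
    - [0.0445, 0.0036, 0.5288, 0.0]
    - [0.0017, 0.0008, 0.0132, 0.2389]

neuron:
  tau_m_ms: 10.0             # membrane time constant
  c_m_pf: 250.0              # membrane capacitance
  e_l_mv: -65.0              # leak / resting potential
  v_th_mv: -50.0             # spike threshold
  v_reset_mv: -65.0          # post-spike reset
  t_ref_ms: 2.0              # absolute refractory period
  tau_syn_ms: 0.5            # exponential PSC time constant

synapse:
  w_exc_pa: 87.8             # base excitatory weight (PSC amplitude)
  g: 4.0                     # inhibitory weight = -g * w_exc
  intra_mc_weight_scale: 1.6 # all intra-microcircuit synapses rescaled by this
  w_input_pa: 1400.0         # sensory/attentional/noise fiber weight, calibrated
                             # to give clear orientation tuning and attentional
                             # modulation; never rescaled with network size
  delay_exc_mean_ms: 1.5
  delay_exc_sd_ms: 0.75
  delay_inh_mean_ms: 0.8
  delay_inh_sd_ms: 0.4

inter_mc:
  p_lateral_inhibition: 0.03 # L2/3e(a) -> L2/3i(b) for every b != a
  p_similar_excitation: 0.06 # L2/3e(a) -> L2/3e(b) for ring-adjacent b
  similar_max_ring_distance: 1
  enable_exc_exc: true       # false = modified (ablated) model

background:                  # independent excitatory Poisson drive per neuron
  rates_hz:                  # rate of each background fiber, per population;
    L23e: 5.24               # calibrated (mean-field solve + closed-loop
    L23i: 4.943              # refinement) so the background-only network sits
    L4e:  4.632              # near the model's spontaneous layer rates
    L4i:  3.47
    L5e:  4.629
    L5i:  4.192
    L6e:  2.534
    L6i:  3.744
  fibers:                    # fibers converging on one neuron, per population
    L23e: 1600
    L23i: 1500
    L4e:  2100
    L4i:  1900
    L5e:  2000
    L5i:  1900
    L6e:  2900
    L6i:  2100

stimulus:                    # bottom-up oriented-bar drive
  peak_rate_hz: 20.0         # fiber rate at the preferred orientation
  n_fibers: 225              # fibers per microcircuit
  tuning_width_deg: 30.0     # circular-Gaussian falloff width
  floor_rate_hz: 0.0
  projection: {L4e: 0.0983, L4i: 0.0619, L6e: 0.0512, L6i: 0.0196}

attention:                   # top-down drive
  rate_hz: 5.0
  n_fibers_per_layer: 300    # separate 300-fiber bundles for L2/3 and L5
  projection: {L23e: 0.13, L23i: 0.075, L5e: 0.13, L5i: 0.075}

noise:                       # external noise reuses the bottom-up pathway
  n_fibers: 225

simulation:
  dt_ms: 0.1
  warmup_ms: 200.0           # discarded from every analysis
  record_ms: 1000.0          # analysed simulated time per trial

scale:
  k: 1.0                     # population scale factor
  weight_compensation_exponent: 1.0  # weights multiplied by (1/k)**exponent
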