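"""Numba time-stepping kernel for the current-based LIF network.

Sub-threshold dynamics are linear, so each step applies the exact
matrix-exponential propagator of (V, I_syn):

    I(t+dt) = I(t) * exp(-dt/tau_s) + arriving PSC jumps
    V(t+dt) = V_inf + (V(t) - V_inf) * exp(-dt/tau_m) + P21 * I(t)

with V_inf = E_L + R_m * I_ext and
P21 = (tau_s * tau_m) / (C_m * (tau_m - tau_s)) * (exp(-dt/tau_m) - exp(-dt/tau_s)).

Spikes are thresholded on the grid, the potential is clamped at reset during
the refractory period, and synaptic events are delivered through a circular
delay buffer.  External Poisson drive (aggregated background per neuron plus
explicit fiber ensembles) is drawn by inverse transform from per-rate-class
CDF tables using an inline xorshift128+ generator, seeded once per call, so
identical arguments give bit-identical spikes.  The CDF tables are truncated
where the survival probability falls below ~1e-12.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_DOUBLE_SCALE = 1.0 / 9007199254740992.0  # 2^-53


@njit(inline="always")
def _next_u64(state):
    """xorshift128+ step on a 2-element uint64 state array."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << _U64(23)
    s1 ^= s1 >> _U64(17)
    s1 ^= s0 ^ (s0 >> _U64(26))
    state[1] = s1
    return s0 + s1


@njit(inline="always")
def _uniform(state):
    return float(_next_u64(state) >> _U64(11)) * _DOUBLE_SCALE


@njit(cache=True)
def _seed_state(seed):
    """Expand an integer seed into a nonzero xorshift state (splitmix64)."""
    state = np.empty(2, np.uint64)
    x = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = x
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
        z = z ^ (z >> _U64(31))
        state[i] = z if z != _U64(0) else _U64(0x1234567887654321)
        x += _U64(0x9E3779B97F4A7C15)
    return state


@njit(inline="always")
def _pois(state, cdf, row, kmax):
    """Inverse-transform Poisson draw from a precomputed CDF row."""
    u = _uniform(state)
    k = 0
    while k < kmax and u > cdf[row, k]:
        k += 1
    return k


@njit(cache=True)
def run_lif(
    seed,
    steps,
    n,
    e_m,            # exp(-dt/tau_m)
    e_s,            # exp(-dt/tau_s)
    p21,
    r_m,            # tau_m / C_m  (mV per pA)
    theta,
    v_reset,
    e_l,
    ref_steps,
    indptr,         # recurrent out-CSR
    targets,
    weights,
    delay_steps,
    max_delay,
    bg_class,       # (G, n) int32 rate-class index per neuron, -1 = silent
    bg_w,           # (G,) weight per background group, pA
    f_class,        # (F,) rate-class index per fiber, -1 = silent
    f_w,            # (F,) weight per fiber, pA
    f_indptr,       # fiber -> target CSR
    f_targets,
    pois_cdf,       # (n_classes, kmax) Poisson CDF table
    i_ext,          # (n,) constant current, pA
    v0,             # (n,) initial potential, mV
    spike_cap,
):
    V = v0.copy()
    I = np.zeros(n)
    ref = np.zeros(n, np.int64)
    D = max_delay + 1
    buf = np.zeros((D, n))
    sp_id = np.empty(spike_cap, np.int32)
    sp_t = np.empty(spike_cap, np.int32)
    ns = 0
    G = bg_class.shape[0]
    F = f_class.shape[0]
    kmax = pois_cdf.shape[1]
    state = _seed_state(seed)
    bad_step = -1
    for step in range(steps):
        cur = step % D
        nxt = (step + 1) % D
        row = buf[cur]
        for i in range(n):
            arr = row[i]
            row[i] = 0.0
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = v_reset
                I[i] = I[i] * e_s + arr
            else:
                v_inf = e_l + r_m * i_ext[i]
                v = v_inf + (V[i] - v_inf) * e_m + p21 * I[i]
                I[i] = I[i] * e_s + arr
                if v >= theta:
                    if ns < spike_cap:
                        sp_id[ns] = i
                        sp_t[ns] = step
                    ns += 1
                    v = v_reset
                    ref[i] = ref_steps
                    for e in range(indptr[i], indptr[i + 1]):
                        buf[(step + delay_steps[e]) % D, targets[e]] += weights[e]
                V[i] = v
        nrow = buf[nxt]
        for g in range(G):
            w = bg_w[g]
            cls = bg_class[g]
            for i in range(n):
                c = cls[i]
                if c >= 0:
                    k = _pois(state, pois_cdf, c, kmax)
                    if k > 0:
                        nrow[i] += w * k
        for f in range(F):
            c = f_class[f]
            if c >= 0:
                k = _pois(state, pois_cdf, c, kmax)
                if k > 0:
                    inc = f_w[f] * k
                    for e in range(f_indptr[f], f_indptr[f + 1]):
                        nrow[f_targets[e]] += inc
        if step % 200 == 0:
            ok = True
            for i in range(n):
                if not np.isfinite(V[i]):
                    ok = False
            if not ok:
                bad_step = step
                break
    stored = ns if ns < spike_cap else spike_cap
    return sp_id[:stored], sp_t[:stored], ns, bad_step
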