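"""Numba kernels for pairwise-Bernoulli connectivity sampling.

A postsynaptic neuron receives a synapse from each eligible presynaptic
neuron independently with probability C (no multapses; no autapses).  The
sampler draws, per postsynaptic neuron, an in-degree from Binomial(N_avail, C)
and then a uniform distinct subset of presynaptic partners, which is exactly
equivalent to flipping the N_pre x N_post Bernoulli coins but runs in time
proportional to the number of realized edges.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sample_pathway(seed, n_pre, n_post, c, exclude_diagonal):
    """Edge list (pre_idx, post_idx) for one pathway, local 0-based indices.

    ``exclude_diagonal`` removes the (i, i) pairs; use it when pre and post
    are the same population (autapses disallowed).
    """
    np.random.seed(seed)
    n_avail = n_pre - 1 if exclude_diagonal else n_pre
    deg = np.empty(n_post, np.int64)
    total = 0
    for j in range(n_post):
        d = np.random.binomial(n_avail, c) if n_avail > 0 and c > 0.0 else 0
        deg[j] = d
        total += d
    pre = np.empty(total, np.int32)
    post = np.empty(total, np.int32)
    mark = np.zeros(n_pre, np.bool_)
    chosen = np.empty(max(n_avail, 1), np.int64)
    idx = 0
    for j in range(n_post):
        k = deg[j]
        cnt = 0
        while cnt < k:
            r = np.random.randint(0, n_avail)
            m = r + 1 if (exclude_diagonal and r >= j) else r
            if not mark[m]:
                mark[m] = True
                chosen[cnt] = m
                cnt += 1
        for t in range(k):
            pre[idx] = chosen[t]
            post[idx] = j
            mark[chosen[t]] = False
            idx += 1
    return pre, post


def sample_pathway_bruteforce(rng, n_pre, n_post, c, exclude_diagonal):
    """Literal pairwise-Bernoulli reference (O(N_pre * N_post)); oracle use."""
    coins = rng.random((n_pre, n_post)) < c
    if exclude_diagonal:
        np.fill_diagonal(coins, False)
    pre, post = np.nonzero(coins)
    order = np.lexsort((pre, post))  # group by post like the fast sampler
    return pre[order].astype(np.int32), post[order].astype(np.int32)
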