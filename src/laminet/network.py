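"""Realize a :class:`~laminet.config.ModelSpec` as neurons and synapses.

Neuron ids are dense and laid out microcircuit-major, population order
L2/3e, L2/3i, L4e, L4i, L5e, L5i, L6e, L6i.  Wiring is reproducible from a
seed: every (microcircuit, pathway) pair draws from its own substream, so a
microcircuit's internal wiring does not depend on ring labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._sampling import sample_pathway
from .config import POPULATIONS, ModelSpec

#: substream tags: 0..63 intra-mc pathways, then inter-mc pathways
_INTER_EI_TAG = 1000
_INTER_EE_TAG = 2000

#: default refusal threshold for full builds (edges); ~3 GiB of edge arrays
DEFAULT_MAX_EDGES = 400_000_000


class NetworkSizeError(MemoryError):
    """Estimated synapse count exceeds the configured cap."""


@dataclass
class Network:
    """Neuron populations plus a flat synapse edge list."""

    spec_hash: str
    seed: int
    n_neurons: int
    n_mc: int
    pop_sizes: dict[str, int]
    pre: np.ndarray        # int32 global pre ids
    post: np.ndarray       # int32 global post ids
    weight: np.ndarray     # float32, pA (negative for inhibitory sources)
    delay: np.ndarray      # float32, ms
    _csr: tuple | None = field(default=None, repr=False)

    # -- id layout ----------------------------------------------------------

    @property
    def mc_size(self) -> int:
        return sum(self.pop_sizes.values())

    def pop_slice(self, mc: int, pop: str) -> slice:
        """Global id range of one population of one microcircuit."""
        start = mc * self.mc_size
        for p in POPULATIONS:
            if p == pop:
                return slice(start, start + self.pop_sizes[p])
            start += self.pop_sizes[p]
        raise KeyError(pop)

    def pop_gids(self, mc: int, pop: str) -> np.ndarray:
        s = self.pop_slice(mc, pop)
        return np.arange(s.start, s.stop, dtype=np.int64)

    def neuron_table(self) -> pd.DataFrame:
        """One row per neuron: gid, mc, layer, cell_type, local_index."""
        rows = []
        for mc in range(self.n_mc):
            for pop in POPULATIONS:
                s = self.pop_slice(mc, pop)
                n = s.stop - s.start
                rows.append(
                    pd.DataFrame(
                        {
                            "gid": np.arange(s.start, s.stop),
                            "mc": mc,
                            "layer": pop[:-1],
                            "cell_type": pop[-1],
                            "local_index": np.arange(n),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    # -- derived ------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)

    @property
    def min_delay_ms(self) -> float:
        return float(self.delay.min()) if self.delay.size else np.inf

    def out_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(indptr, targets, weights, delays) grouped by presynaptic id."""
        if self._csr is None:
            order = np.argsort(self.pre, kind="stable")
            counts = np.bincount(self.pre, minlength=self.n_neurons)
            indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            self._csr = (
                indptr,
                self.post[order].astype(np.int32),
                self.weight[order].astype(np.float32),
                self.delay[order].astype(np.float32),
            )
        return self._csr

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arr in (self.pre, self.post, self.weight, self.delay):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    # -- text I/O -----------------------------------------------------------

    def save_edges(self, path: str | Path) -> None:
        """Delimited edge list with a provenance header block."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# laminet edge list\n# seed={self.seed}\n")
            fh.write(f"# spec_hash={self.spec_hash}\n")
            fh.write(f"# n_neurons={self.n_neurons} n_mc={self.n_mc}\n")
            fh.write(
                "# pop_sizes=" + ",".join(f"{p}:{self.pop_sizes[p]}" for p in POPULATIONS) + "\n"
            )
            fh.write("pre_id\tpost_id\tweight_pA\tdelay_ms\n")
            df = pd.DataFrame(
                {
                    "pre_id": self.pre,
                    "post_id": self.post,
                    "weight_pA": self.weight,
                    "delay_ms": self.delay,
                }
            )
            df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")

    @classmethod
    def load_edges(cls, path: str | Path) -> "Network":
        path = Path(path)
        meta: dict[str, str] = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    skip += 1
                    body = line[1:].strip()
                    for tok in body.split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                else:
                    break
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        pop_sizes = {}
        for item in meta["pop_sizes"].split(","):
            k, v = item.split(":")
            pop_sizes[k] = int(v)
        n_mc = int(meta["n_mc"])
        return cls(
            spec_hash=meta["spec_hash"],
            seed=int(meta["seed"]),
            n_neurons=int(meta["n_neurons"]),
            n_mc=n_mc,
            pop_sizes=pop_sizes,
            pre=df["pre_id"].to_numpy(np.int32),
            post=df["post_id"].to_numpy(np.int32),
            weight=df["weight_pA"].to_numpy(np.float32),
            delay=df["delay_ms"].to_numpy(np.float32),
        )


# ---------------------------------------------------------------------------
# sampling


def _substream_seed(seed: int, *tags: int) -> int:
    """Deterministic 31-bit seed for a keyed substream."""
    ss = np.random.SeedSequence([int(seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def sample_connections(
    n_pre: int,
    n_post: int,
    c: float,
    seed: int,
    same_population: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-Bernoulli edge sample between two populations.

    Returns local (pre_idx, post_idx) arrays; each ordered pair with
    pre != post (when ``same_population``) is connected independently with
    probability ``c``.  No multapses, no autapses.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"connection probability {c} outside [0, 1]")
    if n_pre <= 0 or n_post <= 0:
        raise ValueError("populations must be non-empty")
    if c == 0.0:
        return np.empty(0, np.int32), np.empty(0, np.int32)
    return sample_pathway(seed, n_pre, n_post, c, same_population)


def _draw_delays(rng: np.random.Generator, n: int, mean: float, sd: float,
                 floor_ms: float) -> np.ndarray:
    """Truncated-normal delays: normal jitter clipped at one step from below."""
    d = rng.normal(mean, sd, size=n)
    return np.maximum(d, floor_ms).astype(np.float32)


def _expected_intra_edges(spec: ModelSpec) -> float:
    total = 0.0
    for pre_pop in POPULATIONS:
        for post_pop in POPULATIONS:
            c = spec.connectivity.prob(pre_pop, post_pop)
            total += c * spec.population_size(pre_pop) * spec.population_size(post_pop)
    return total


def estimate_edge_count(spec: ModelSpec) -> float:
    """Expected synapse count of the full network (guards full builds)."""
    n = spec.ring.n
    intra = n * _expected_intra_edges(spec)
    n_e = spec.population_size("L23e")
    n_i = spec.population_size("L23i")
    inter = n * (n - 1) * n_e * n_i * spec.inter_mc.p_lateral_inhibition
    if spec.inter_mc.enable_exc_exc:
        d = spec.inter_mc.similar_max_ring_distance
        neighbors = min(2 * d, n - 1)
        inter += n * neighbors * n_e * n_e * spec.inter_mc.p_similar_excitation
    return intra + inter


def build_intra_mc(spec: ModelSpec, mc: int, seed: int, dt_floor_ms: float = 0.1):
    """Wire all 64 population pairs inside one microcircuit.

    Returns (pre, post, weight, delay) arrays with global ids.
    """
    mc_sizes = {p: spec.population_size(p) for p in POPULATIONS}
    mc_size = sum(mc_sizes.values())
    offsets = {}
    off = mc * mc_size
    for p in POPULATIONS:
        offsets[p] = off
        off += mc_sizes[p]

    pres, posts, weights, delays = [], [], [], []
    pathway_tag = 0
    for pre_pop in POPULATIONS:
        for post_pop in POPULATIONS:
            c = spec.connectivity.prob(pre_pop, post_pop)
            pathway_tag += 1
            if c == 0.0:
                continue
            sub = _substream_seed(seed, mc, pathway_tag)
            pre_idx, post_idx = sample_connections(
                mc_sizes[pre_pop], mc_sizes[post_pop], c, sub,
                same_population=(pre_pop == post_pop),
            )
            n = pre_idx.size
            if n == 0:
                continue
            pre_ct = pre_pop[-1]
            w = spec.recurrent_weight_pa(pre_ct, intra_mc=True)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), mc, pathway_tag, 7])
            )
            if pre_ct == "e":
                d = _draw_delays(rng, n, spec.synapse.delay_exc_mean_ms,
                                 spec.synapse.delay_exc_sd_ms, dt_floor_ms)
            else:
                d = _draw_delays(rng, n, spec.synapse.delay_inh_mean_ms,
                                 spec.synapse.delay_inh_sd_ms, dt_floor_ms)
            pres.append(pre_idx.astype(np.int32) + offsets[pre_pop])
            posts.append(post_idx.astype(np.int32) + offsets[post_pop])
            weights.append(np.full(n, w, dtype=np.float32))
            delays.append(d)
    return _concat(pres, posts, weights, delays)


def build_inter_mc(spec: ModelSpec, seed: int, dt_floor_ms: float = 0.1):
    """Wire the ring: lateral inhibition plus similar-orientation excitation.

    For every ordered microcircuit pair (a, b), a != b, L2/3e(a) -> L2/3i(b)
    with the lateral-inhibition probability; for ring-adjacent pairs
    L2/3e(a) -> L2/3e(b) with the similar-excitation probability (omitted in
    the ablated model).
    """
    n_mc = spec.ring.n
    mc_sizes = {p: spec.population_size(p) for p in POPULATIONS}
    mc_size = sum(mc_sizes.values())

    def offset(mc: int, pop: str) -> int:
        off = mc * mc_size
        for p in POPULATIONS:
            if p == pop:
                return off
            off += mc_sizes[p]
        raise KeyError(pop)

    n_e = mc_sizes["L23e"]
    n_i = mc_sizes["L23i"]
    w_exc = spec.recurrent_weight_pa("e", intra_mc=False)
    pres, posts, weights, delays = [], [], [], []
    for a in range(n_mc):
        for b in range(n_mc):
            if a == b:
                continue
            # lateral inhibition pathway: E(a) -> I(b)
            sub = _substream_seed(seed, _INTER_EI_TAG, a, b)
            pre_idx, post_idx = sample_connections(
                n_e, n_i, spec.inter_mc.p_lateral_inhibition, sub
            )
            if pre_idx.size:
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), _INTER_EI_TAG, a, b, 7])
                )
                d = _draw_delays(rng, pre_idx.size, spec.synapse.delay_exc_mean_ms,
                                 spec.synapse.delay_exc_sd_ms, dt_floor_ms)
                pres.append(pre_idx.astype(np.int32) + offset(a, "L23e"))
                posts.append(post_idx.astype(np.int32) + offset(b, "L23i"))
                weights.append(np.full(pre_idx.size, w_exc, dtype=np.float32))
                delays.append(d)
            # similar-orientation excitation: E(a) -> E(b), ring neighbors
            if (
                spec.inter_mc.enable_exc_exc
                and spec.ring.ring_distance(a, b) <= spec.inter_mc.similar_max_ring_distance
            ):
                sub = _substream_seed(seed, _INTER_EE_TAG, a, b)
                pre_idx, post_idx = sample_connections(
                    n_e, n_e, spec.inter_mc.p_similar_excitation, sub
                )
                if pre_idx.size:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([int(seed), _INTER_EE_TAG, a, b, 7])
                    )
                    d = _draw_delays(rng, pre_idx.size, spec.synapse.delay_exc_mean_ms,
                                     spec.synapse.delay_exc_sd_ms, dt_floor_ms)
                    pres.append(pre_idx.astype(np.int32) + offset(a, "L23e"))
                    posts.append(post_idx.astype(np.int32) + offset(b, "L23e"))
                    weights.append(np.full(pre_idx.size, w_exc, dtype=np.float32))
                    delays.append(d)
    return _concat(pres, posts, weights, delays)


def _concat(pres, posts, weights, delays):
    if not pres:
        e = np.empty(0, np.int32)
        return e, e.copy(), np.empty(0, np.float32), np.empty(0, np.float32)
    return (
        np.concatenate(pres),
        np.concatenate(posts),
        np.concatenate(weights),
        np.concatenate(delays),
    )


def build_network(
    spec: ModelSpec,
    seed: int,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> Network:
    """Realize the full 8-microcircuit network from a seed."""
    est = estimate_edge_count(spec)
    if est > max_edges:
        raise NetworkSizeError(
            f"estimated {est:.2e} synapses exceeds cap {max_edges:.2e}; "
            "reduce the network with scale_spec(spec, k) or raise max_edges"
        )
    dt_floor = float(spec.simulation.get("dt_ms", 0.1))
    parts = [build_intra_mc(spec, mc, seed, dt_floor) for mc in range(spec.ring.n)]
    parts.append(build_inter_mc(spec, seed, dt_floor))
    pre = np.concatenate([p[0] for p in parts])
    post = np.concatenate([p[1] for p in parts])
    weight = np.concatenate([p[2] for p in parts])
    delay = np.concatenate([p[3] for p in parts])
    pop_sizes = {p: spec.population_size(p) for p in POPULATIONS}
    return Network(
        spec_hash=spec.spec_hash(),
        seed=int(seed),
        n_neurons=spec.total_neurons,
        n_mc=spec.ring.n,
        pop_sizes=pop_sizes,
        pre=pre,
        post=post,
        weight=weight,
        delay=delay,
    )
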