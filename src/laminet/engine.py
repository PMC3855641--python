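"""LIF network simulation with exponential-current synapses and Poisson drive.

Two interchangeable backends integrate the same dynamics: a numba kernel
(``backend="numba"``, the default) and a vectorized numpy reference
(``backend="numpy"``) used for cross-checks on small fixtures.  Within a
backend, identical ``(network, inputs, duration, dt, seed)`` produce
bit-identical spike data; the two backends agree at the level of firing
statistics (their RNG streams differ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernel
from ._sampling import sample_pathway
from .config import POPULATIONS, ModelSpec
from .network import Network, _substream_seed


class SimulationConfigError(ValueError):
    """Invalid simulation setup (e.g. dt larger than the minimum delay)."""


class NumericalError(RuntimeError):
    """Non-finite state encountered; carries the offending step index."""


@dataclass
class InputEnsemble:
    """A labelled ensemble of independent excitatory Poisson fibers.

    Two realizations exist.  *Explicit* ensembles carry a sampled
    fiber-to-neuron wiring (``fiber_idx`` / ``fiber_target_gids``): stimulus,
    attention and noise fibers are shared by many neurons, so their identity
    matters.  *Private* ensembles (``fiber_idx is None``) model ``n_fibers``
    independent fibers converging on each listed neuron, which is exactly an
    independent Poisson drive of rate ``n_fibers * rate_hz`` per neuron; the
    background drive uses this form.
    """

    label: str
    rate_hz: float                      # rate per fiber
    n_fibers: int
    weight_pa: float
    fiber_idx: np.ndarray | None = None        # edge list: fiber index ...
    fiber_target_gids: np.ndarray | None = None  # ... -> target neuron gid
    target_gids: np.ndarray | None = None      # private mode targets

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("ensemble rate must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("fiber count must be >= 0")

    @property
    def is_private(self) -> bool:
        return self.fiber_idx is None

    @classmethod
    def from_projection(
        cls,
        label: str,
        rate_hz: float,
        n_fibers: int,
        weight_pa: float,
        target_groups: Sequence[tuple[np.ndarray, float]],
        seed: int,
    ) -> "InputEnsemble":
        """Sample fiber->neuron wiring: each (fiber, neuron) pair of a target
        group connects independently with the group's probability."""
        fibers, gids = [], []
        for gi, (group_gids, p) in enumerate(target_groups):
            if p == 0.0 or len(group_gids) == 0 or n_fibers == 0:
                continue
            sub = _substream_seed(seed, 17, gi)
            f_idx, t_idx = sample_pathway(sub, n_fibers, len(group_gids), p, False)
            fibers.append(f_idx)
            gids.append(np.asarray(group_gids, dtype=np.int64)[t_idx])
        if fibers:
            fiber_idx = np.concatenate(fibers).astype(np.int32)
            target = np.concatenate(gids).astype(np.int32)
        else:
            fiber_idx = np.empty(0, np.int32)
            target = np.empty(0, np.int32)
        return cls(
            label=label,
            rate_hz=rate_hz,
            n_fibers=n_fibers,
            weight_pa=weight_pa,
            fiber_idx=fiber_idx,
            fiber_target_gids=target,
        )


@dataclass
class SpikeData:
    """Timestamped spike events of one simulation run."""

    gids: np.ndarray          # int32 neuron ids, time-ordered
    times_ms: np.ndarray      # float64 spike times on the dt grid
    duration_ms: float
    n_neurons: int
    dt_ms: float
    seed: int = 0
    v_mean: np.ndarray | None = field(default=None, repr=False)

    def counts(self, gids: np.ndarray, t0: float, t1: float) -> np.ndarray:
        """Per-neuron spike counts within [t0, t1) for the given gid set."""
        gids = np.asarray(gids)
        sel = (self.times_ms >= t0) & (self.times_ms < t1)
        all_counts = np.bincount(self.gids[sel], minlength=self.n_neurons)
        return all_counts[gids]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                f"# laminet spikes\n# n_neurons={self.n_neurons} "
                f"duration_ms={self.duration_ms} dt_ms={self.dt_ms} seed={self.seed}\n"
            )
            fh.write("gid\ttime_ms\n")
            for g, t in zip(self.gids, self.times_ms):
                fh.write(f"{g}\t{t:.4f}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SpikeData":
        import pandas as pd

        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    skip += 1
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                else:
                    break
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(
            gids=df["gid"].to_numpy(np.int32),
            times_ms=df["time_ms"].to_numpy(float),
            duration_ms=float(meta["duration_ms"]),
            n_neurons=int(meta["n_neurons"]),
            dt_ms=float(meta["dt_ms"]),
            seed=int(meta["seed"]),
        )


def attach_background(net: Network, spec: ModelSpec) -> list[InputEnsemble]:
    """One private excitatory Poisson ensemble per population (all mcs)."""
    out = []
    for pop in POPULATIONS:
        gids = np.concatenate([net.pop_gids(mc, pop) for mc in range(net.n_mc)])
        out.append(
            InputEnsemble(
                label=f"background:{pop}",
                rate_hz=spec.background.rates_hz[pop],
                n_fibers=spec.background.fibers[pop],
                weight_pa=spec.background_weight_pa,
                target_gids=gids,
            )
        )
    return out


# ---------------------------------------------------------------------------


def _prepare(net: Network, inputs: Sequence[InputEnsemble], dt: float):
    indptr, targets, weights, delays = net.out_csr()
    if net.n_edges:
        if dt > net.min_delay_ms + 1e-12:
            raise SimulationConfigError(
                f"dt={dt} ms exceeds minimum synaptic delay {net.min_delay_ms} ms"
            )
        delay_steps = np.maximum(np.rint(delays / dt), 1).astype(np.int32)
        max_delay = int(delay_steps.max())
    else:
        delay_steps = np.empty(0, np.int32)
        max_delay = 1

    n = net.n_neurons
    # group private ensembles by weight -> aggregated per-neuron rates
    groups: dict[float, np.ndarray] = {}
    f_lam_parts, f_w_parts, f_edges = [], [], []
    fiber_offset = 0
    for ens in inputs:
        if ens.is_private:
            lam = groups.setdefault(float(ens.weight_pa), np.zeros(n))
            lam[ens.target_gids] += ens.rate_hz * ens.n_fibers * dt / 1000.0
        else:
            nf = ens.n_fibers
            f_lam_parts.append(np.full(nf, ens.rate_hz * dt / 1000.0))
            f_w_parts.append(np.full(nf, ens.weight_pa))
            if ens.fiber_idx.size:
                f_edges.append(
                    (ens.fiber_idx.astype(np.int64) + fiber_offset,
                     ens.fiber_target_gids)
                )
            fiber_offset += nf
    if groups:
        bg_w = np.array(sorted(groups), dtype=np.float64)
        bg_lam = np.stack([groups[w] for w in bg_w])
    else:
        bg_w = np.empty(0)
        bg_lam = np.empty((0, n))
    if f_lam_parts:
        f_lam = np.concatenate(f_lam_parts)
        f_w = np.concatenate(f_w_parts)
    else:
        f_lam = np.empty(0)
        f_w = np.empty(0)
    nf_total = fiber_offset
    if f_edges:
        fe_fiber = np.concatenate([e[0] for e in f_edges])
        fe_target = np.concatenate([e[1] for e in f_edges]).astype(np.int32)
        order = np.argsort(fe_fiber, kind="stable")
        fe_fiber = fe_fiber[order]
        fe_target = fe_target[order]
        counts = np.bincount(fe_fiber, minlength=nf_total)
        f_indptr = np.zeros(nf_total + 1, dtype=np.int64)
        np.cumsum(counts, out=f_indptr[1:])
        f_targets = fe_target
    else:
        f_indptr = np.zeros(nf_total + 1, dtype=np.int64)
        f_targets = np.empty(0, np.int32)
    return (
        indptr, targets, weights, delay_steps, max_delay,
        bg_lam, bg_w, f_lam, f_w, f_indptr, f_targets,
    )


def _poisson_tables(bg_lam: np.ndarray, f_lam: np.ndarray):
    """Rate-class indices and a shared truncated Poisson CDF table.

    Rates repeat heavily (one value per population / fiber bundle), so each
    distinct per-step mean gets one CDF row; rows are truncated where the
    survival probability drops below ~1e-12.
    """
    from scipy import stats as _stats

    values = np.concatenate([bg_lam.ravel(), f_lam])
    nonzero = np.unique(values[values > 0])
    if nonzero.size == 0:
        cdf = np.ones((1, 1))
        return (
            np.full(bg_lam.shape, -1, np.int32),
            np.full(f_lam.shape, -1, np.int32),
            cdf,
        )
    kmax = int(np.ceil(nonzero.max() + 12.0 * np.sqrt(nonzero.max()) + 10.0))
    cdf = _stats.poisson.cdf(np.arange(kmax)[None, :], nonzero[:, None])

    def classify(lam):
        cls = np.full(lam.shape, -1, np.int32)
        nz = lam > 0
        cls[nz] = np.searchsorted(nonzero, lam[nz]).astype(np.int32)
        return cls

    return classify(bg_lam), classify(f_lam), np.ascontiguousarray(cdf)


def simulate(
    net: Network,
    inputs: Sequence[InputEnsemble],
    duration_ms: float,
    dt_ms: float | None = None,
    seed: int = 0,
    backend: str = "numba",
    i_ext_pa: np.ndarray | float = 0.0,
    v_init_mv: np.ndarray | float | None = None,
    neuron=None,
    record_v_mean: bool = False,
) -> SpikeData:
    """Integrate the network for ``duration_ms`` and return its spikes.

    ``neuron`` is the :class:`~laminet.config.NeuronParams` to use; pass the
    owning spec's.  ``i_ext_pa`` injects a constant current (scalar or per
    neuron).  ``record_v_mean`` (numpy backend only) additionally returns the
    time-averaged membrane potential per neuron.
    """
    if neuron is None:
        raise ValueError("neuron parameters are required (spec.neuron)")
    if duration_ms <= 0:
        raise SimulationConfigError("duration must be > 0")
    dt = float(dt_ms) if dt_ms is not None else 0.1
    steps = int(round(duration_ms / dt))
    n = net.n_neurons

    e_m = math.exp(-dt / neuron.tau_m_ms)
    e_s = math.exp(-dt / neuron.tau_syn_ms)
    if abs(neuron.tau_m_ms - neuron.tau_syn_ms) < 1e-9:
        # degenerate equal-time-constant limit of the propagator
        p21 = dt / neuron.c_m_pf * math.exp(-dt / neuron.tau_m_ms)
    else:
        p21 = (
            neuron.tau_syn_ms * neuron.tau_m_ms
            / (neuron.c_m_pf * (neuron.tau_m_ms - neuron.tau_syn_ms))
            * (e_m - e_s)
        )
    r_m = neuron.tau_m_ms / neuron.c_m_pf
    ref_steps = int(round(neuron.t_ref_ms / dt))

    i_ext = np.broadcast_to(np.asarray(i_ext_pa, dtype=float), (n,)).copy()
    if v_init_mv is None:
        v0 = np.full(n, neuron.e_l_mv)
    else:
        v0 = np.broadcast_to(np.asarray(v_init_mv, dtype=float), (n,)).copy()

    (indptr, targets, weights, delay_steps, max_delay,
     bg_lam, bg_w, f_lam, f_w, f_indptr, f_targets) = _prepare(net, inputs, dt)

    if backend == "numba":
        bg_class, f_class, pois_cdf = _poisson_tables(bg_lam, f_lam)
        cap = max(100_000, int(n * duration_ms / 1000.0 * 200))
        while True:
            sp_id, sp_t, ns, bad = _kernel.run_lif(
                int(seed) % (2**31 - 1), steps, n,
                e_m, e_s, p21, r_m,
                neuron.v_th_mv, neuron.v_reset_mv, neuron.e_l_mv, ref_steps,
                indptr, targets, weights, delay_steps, max_delay,
                bg_class, bg_w,
                f_class, f_w, f_indptr, f_targets,
                pois_cdf, i_ext, v0, cap,
            )
            if bad >= 0:
                raise NumericalError(f"non-finite membrane state at step {bad}")
            if ns <= cap:
                break
            cap = int(ns * 1.2) + 1000
        v_mean = None
    elif backend == "numpy":
        sp_id, sp_t, v_mean = _run_numpy(
            int(seed), steps, n, e_m, e_s, p21, r_m,
            neuron.v_th_mv, neuron.v_reset_mv, neuron.e_l_mv, ref_steps,
            indptr, targets, weights, delay_steps, max_delay,
            bg_lam, bg_w, f_lam, f_w, f_indptr, f_targets,
            i_ext, v0, record_v_mean,
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    times = (np.asarray(sp_t, dtype=np.int64) + 1) * dt  # spike at end of step
    return SpikeData(
        gids=np.asarray(sp_id, np.int32),
        times_ms=times.astype(float),
        duration_ms=steps * dt,
        n_neurons=n,
        dt_ms=dt,
        seed=int(seed),
        v_mean=v_mean if record_v_mean else None,
    )


def _run_numpy(
    seed, steps, n, e_m, e_s, p21, r_m, theta, v_reset, e_l, ref_steps,
    indptr, targets, weights, delay_steps, max_delay,
    bg_lam, bg_w, f_lam, f_w, f_indptr, f_targets,
    i_ext, v0, record_v_mean,
):
    rng = np.random.default_rng(seed)
    V = v0.copy()
    I = np.zeros(n)
    ref = np.zeros(n, np.int64)
    D = max_delay + 1
    buf = np.zeros((D, n))
    sp_id_parts, sp_t_parts = [], []
    v_sum = np.zeros(n) if record_v_mean else None
    v_inf = e_l + r_m * i_ext
    for step in range(steps):
        cur = step % D
        nxt = (step + 1) % D
        arr = buf[cur].copy()
        buf[cur] = 0.0
        refractory = ref > 0
        ref[refractory] -= 1
        V = np.where(refractory, v_reset, v_inf + (V - v_inf) * e_m + p21 * I)
        I = I * e_s + arr
        if not np.all(np.isfinite(V)):
            raise NumericalError(f"non-finite membrane state at step {step}")
        spk = np.nonzero((ref == 0) & (V >= theta))[0]
        if spk.size:
            sp_id_parts.append(spk.astype(np.int32))
            sp_t_parts.append(np.full(spk.size, step, np.int32))
            V[spk] = v_reset
            ref[spk] = ref_steps
            for i in spk:
                lo, hi = indptr[i], indptr[i + 1]
                slots = (step + delay_steps[lo:hi]) % D
                np.add.at(buf, (slots, targets[lo:hi]), weights[lo:hi])
        if bg_lam.shape[0]:
            counts = rng.poisson(bg_lam)
            buf[nxt] += (counts * bg_w[:, None]).sum(axis=0)
        if f_lam.size:
            fc = rng.poisson(f_lam)
            for f in np.nonzero(fc)[0]:
                lo, hi = f_indptr[f], f_indptr[f + 1]
                np.add.at(buf[nxt], f_targets[lo:hi], f_w[f] * fc[f])
        if record_v_mean:
            v_sum += V
    sp_id = np.concatenate(sp_id_parts) if sp_id_parts else np.empty(0, np.int32)
    sp_t = np.concatenate(sp_t_parts) if sp_t_parts else np.empty(0, np.int32)
    v_mean = v_sum / steps if record_v_mean else None
    return sp_id, sp_t, v_mean
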