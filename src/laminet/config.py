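"""Model parameterization: load, validate, scale and serialize the network spec.

The reference configuration describes eight orientation-selective layered
microcircuits (L2/3, L4, L5, L6; excitatory and inhibitory pools per layer)
that share a receptive field and interact through L2/3.  Every number of the
reference parameterization lives in ``data/defaults.yaml``; a user
configuration only overrides the keys it names.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

LAYERS = ("L23", "L4", "L5", "L6")
CELL_TYPES = ("e", "i")
#: population keys in canonical order (layer-major, excitatory first)
POPULATIONS = tuple(f"{layer}{ct}" for layer in LAYERS for ct in CELL_TYPES)
#: pathway keys of the four connection-probability tables
PATHWAYS = ("ee", "ei", "ie", "ii")

LAYER_LABELS = {"L23": "L2/3", "L4": "L4", "L5": "L5", "L6": "L6"}


class ConfigError(ValueError):
    """A configuration document is missing a key or has an ill-typed value."""


class SpecValidationError(ValueError):
    """A structurally valid configuration violates a model invariant."""


def _defaults_text() -> str:
    return resources.files("laminet.data").joinpath("defaults.yaml").read_text()


def load_defaults() -> dict:
    """Return the packaged reference parameterization as a nested dict."""
    return yaml.safe_load(_defaults_text())


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OrientationRing:
    """The eight preferred orientations, uniformly spaced on [0, 180) deg."""

    n: int = 8

    def __post_init__(self) -> None:
        if self.n != 8:
            raise SpecValidationError("ring.n_orientations must be 8")

    @property
    def spacing_deg(self) -> float:
        return 180.0 / self.n

    @property
    def preferred_orientations(self) -> tuple[float, ...]:
        return tuple(i * self.spacing_deg for i in range(self.n))

    def ring_distance(self, i: int, j: int) -> int:
        """Circular distance on microcircuit indices, in {0..n//2}."""
        d = abs(i - j) % self.n
        return min(d, self.n - d)

    def index_of(self, orientation_deg: float) -> int:
        """Ring index of an orientation; raises if it is not on the ring."""
        idx = (orientation_deg % 180.0) / self.spacing_deg
        if abs(idx - round(idx)) > 1e-9:
            raise ValueError(
                f"orientation {orientation_deg} deg is not one of the "
                f"{self.n} ring orientations"
            )
        return int(round(idx)) % self.n

    def angular_distance(self, a_deg: float, b_deg: float) -> float:
        """Circular orientation distance in degrees, in [0, 90]."""
        d = abs(a_deg - b_deg) % 180.0
        return min(d, 180.0 - d)


@dataclass(frozen=True)
class NeuronParams:
    tau_m_ms: float
    c_m_pf: float
    e_l_mv: float
    v_th_mv: float
    v_reset_mv: float
    t_ref_ms: float
    tau_syn_ms: float

    def __post_init__(self) -> None:
        for name in ("tau_m_ms", "c_m_pf", "t_ref_ms", "tau_syn_ms"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"neuron.{name} must be > 0")
        if self.v_th_mv <= self.v_reset_mv:
            raise SpecValidationError("threshold must exceed reset potential")

    @property
    def r_m_gohm(self) -> float:
        """Membrane resistance tau_m / C_m in GOhm (mV per pA)."""
        return self.tau_m_ms / self.c_m_pf


@dataclass(frozen=True)
class SynapseSpec:
    w_exc_pa: float
    g: float
    intra_mc_weight_scale: float
    w_input_pa: float
    delay_exc_mean_ms: float
    delay_exc_sd_ms: float
    delay_inh_mean_ms: float
    delay_inh_sd_ms: float

    def __post_init__(self) -> None:
        if self.w_exc_pa <= 0:
            raise SpecValidationError("synapse.w_exc_pa must be > 0")
        if self.w_input_pa <= 0:
            raise SpecValidationError("synapse.w_input_pa must be > 0")
        if self.g <= 0:
            raise SpecValidationError("synapse.g must be > 0 (sign is applied)")
        if self.intra_mc_weight_scale <= 0:
            raise SpecValidationError("synapse.intra_mc_weight_scale must be > 0")
        if self.delay_exc_mean_ms <= 0 or self.delay_inh_mean_ms <= 0:
            raise SpecValidationError("synaptic delays must be > 0")

    @property
    def w_inh_pa(self) -> float:
        return -self.g * self.w_exc_pa


@dataclass(frozen=True)
class InterMcSpec:
    p_lateral_inhibition: float = 0.03
    p_similar_excitation: float = 0.06
    similar_max_ring_distance: int = 1
    enable_exc_exc: bool = True

    def __post_init__(self) -> None:
        for name in ("p_lateral_inhibition", "p_similar_excitation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(f"inter_mc.{name}={p} outside [0, 1]")
        if self.similar_max_ring_distance < 1:
            raise SpecValidationError("similar_max_ring_distance must be >= 1")


@dataclass(frozen=True)
class BackgroundSpec:
    """Excitatory background drive: independent Poisson fibers per neuron.

    Each neuron of a population receives its own bundle of ``fibers[pop]``
    independent fibers, each firing at ``rates_hz[pop]``.
    """

    rates_hz: Mapping[str, float]
    fibers: Mapping[str, int]

    def __post_init__(self) -> None:
        for pop in POPULATIONS:
            if pop not in self.fibers:
                raise ConfigError(f"background.fibers missing population {pop}")
            if pop not in self.rates_hz:
                raise ConfigError(f"background.rates_hz missing population {pop}")
            if self.fibers[pop] < 0:
                raise SpecValidationError(f"background.fibers[{pop}] must be >= 0")
            if self.rates_hz[pop] < 0:
                raise SpecValidationError(f"background.rates_hz[{pop}] must be >= 0")

    def rate_per_neuron_hz(self, pop: str) -> float:
        """Aggregate Poisson rate seen by one neuron of a population."""
        return self.rates_hz[pop] * self.fibers[pop]


class ConnectivityTables:
    """Four 4x4 probability matrices C[post_layer, pre_layer] (ee/ei/ie/ii)."""

    def __init__(self, tables: Mapping[str, Any]):
        self._tables: dict[str, np.ndarray] = {}
        for key in PATHWAYS:
            if key not in tables:
                raise ConfigError(f"connectivity.{key} missing")
            mat = np.asarray(tables[key], dtype=float)
            if mat.shape != (4, 4):
                raise ConfigError(f"connectivity.{key} must be a 4x4 table")
            if np.any(mat < 0) or np.any(mat > 1):
                raise SpecValidationError(
                    f"connectivity.{key} has entries outside [0, 1]"
                )
            self._tables[key] = mat

    def table(self, pathway: str) -> np.ndarray:
        return self._tables[pathway].copy()

    def prob(self, pre_pop: str, post_pop: str) -> float:
        """Connection probability from one intra-mc population to another."""
        pre_layer, pre_ct = pre_pop[:-1], pre_pop[-1]
        post_layer, post_ct = post_pop[:-1], post_pop[-1]
        key = pre_ct + post_ct
        # tables are keyed source-type/target-type: ee, ei, ie, ii
        mat = self._tables[key]
        return float(mat[LAYERS.index(post_layer), LAYERS.index(pre_layer)])

    def to_dict(self) -> dict:
        return {k: self._tables[k].tolist() for k in PATHWAYS}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectivityTables):
            return NotImplemented
        return all(
            np.array_equal(self._tables[k], other._tables[k]) for k in PATHWAYS
        )


@dataclass
class ModelSpec:
    """Complete parameterization of the eight-microcircuit network."""

    ring: OrientationRing
    reference_populations: dict[str, int]
    connectivity: ConnectivityTables
    neuron: NeuronParams
    synapse: SynapseSpec
    inter_mc: InterMcSpec
    background: BackgroundSpec
    stimulus: dict = field(default_factory=dict)
    attention: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    scale_k: float = 1.0
    weight_compensation_exponent: float = 1.0
    master_seed: int = 0

    # -- scaling ------------------------------------------------------------

    @property
    def weight_factor(self) -> float:
        """Multiplier on all recurrent weights compensating for downscaling."""
        return (1.0 / self.scale_k) ** self.weight_compensation_exponent

    def population_size(self, pop: str) -> int:
        """Scaled size of one population (round-half-up, at least 1 neuron)."""
        n_ref = self.reference_populations[pop]
        return max(1, int(math.floor(self.scale_k * n_ref + 0.5)))

    @property
    def mc_size(self) -> int:
        return sum(self.population_size(p) for p in POPULATIONS)

    @property
    def total_neurons(self) -> int:
        return self.ring.n * self.mc_size

    # -- weights ------------------------------------------------------------

    def recurrent_weight_pa(self, pre_ct: str, intra_mc: bool) -> float:
        """Synaptic weight for a recurrent connection of the given source type.

        Intra-microcircuit synapses carry the dedicated rescaling factor;
        both intra- and inter-mc synapses carry the scale compensation.
        """
        base = self.synapse.w_exc_pa if pre_ct == "e" else self.synapse.w_inh_pa
        w = base * self.weight_factor
        if intra_mc:
            w *= self.synapse.intra_mc_weight_scale
        return w

    @property
    def background_weight_pa(self) -> float:
        """Weight of background fibers (the base excitatory weight).

        External input strength is not rescaled with the microcircuit.
        """
        return self.synapse.w_exc_pa

    @property
    def input_weight_pa(self) -> float:
        """Weight of sensory / attentional / noise input fibers."""
        return self.synapse.w_input_pa

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        pops = {}
        for layer in LAYERS:
            pops[layer] = {
                "e": self.reference_populations[f"{layer}e"],
                "i": self.reference_populations[f"{layer}i"],
            }
        return {
            "ring": {"n_orientations": self.ring.n},
            "populations": pops,
            "connectivity": self.connectivity.to_dict(),
            "neuron": {
                "tau_m_ms": self.neuron.tau_m_ms,
                "c_m_pf": self.neuron.c_m_pf,
                "e_l_mv": self.neuron.e_l_mv,
                "v_th_mv": self.neuron.v_th_mv,
                "v_reset_mv": self.neuron.v_reset_mv,
                "t_ref_ms": self.neuron.t_ref_ms,
                "tau_syn_ms": self.neuron.tau_syn_ms,
            },
            "synapse": {
                "w_exc_pa": self.synapse.w_exc_pa,
                "g": self.synapse.g,
                "intra_mc_weight_scale": self.synapse.intra_mc_weight_scale,
                "w_input_pa": self.synapse.w_input_pa,
                "delay_exc_mean_ms": self.synapse.delay_exc_mean_ms,
                "delay_exc_sd_ms": self.synapse.delay_exc_sd_ms,
                "delay_inh_mean_ms": self.synapse.delay_inh_mean_ms,
                "delay_inh_sd_ms": self.synapse.delay_inh_sd_ms,
            },
            "inter_mc": {
                "p_lateral_inhibition": self.inter_mc.p_lateral_inhibition,
                "p_similar_excitation": self.inter_mc.p_similar_excitation,
                "similar_max_ring_distance": self.inter_mc.similar_max_ring_distance,
                "enable_exc_exc": self.inter_mc.enable_exc_exc,
            },
            "background": {
                "rates_hz": dict(self.background.rates_hz),
                "fibers": dict(self.background.fibers),
            },
            "stimulus": copy.deepcopy(self.stimulus),
            "attention": copy.deepcopy(self.attention),
            "noise": copy.deepcopy(self.noise),
            "simulation": copy.deepcopy(self.simulation),
            "scale": {
                "k": self.scale_k,
                "weight_compensation_exponent": self.weight_compensation_exponent,
            },
            "master_seed": self.master_seed,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def spec_hash(self) -> str:
        """Stable short hash of the full resolved parameterization."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# loading


def _require(section: Mapping, key: str, typ, where: str):
    if key not in section:
        raise ConfigError(f"missing configuration key: {where}.{key}")
    value = section[key]
    if typ is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if typ is int and isinstance(value, int) and not isinstance(value, bool):
        return value
    if typ is bool and isinstance(value, bool):
        return value
    if not isinstance(value, typ):
        raise ConfigError(
            f"ill-typed configuration key {where}.{key}: "
            f"expected {typ.__name__}, got {type(value).__name__}"
        )
    return value


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_model_spec(config: str | Path | Mapping | None = None) -> ModelSpec:
    """Build a validated :class:`ModelSpec` from a configuration document.

    ``config`` may be a YAML file path, a YAML string, a mapping, or ``None``;
    omitted keys take the packaged reference values.
    """
    defaults = load_defaults()
    if config is None:
        doc: Mapping = {}
    elif isinstance(config, Mapping):
        doc = config
    else:
        text = Path(config).read_text() if Path(str(config)).is_file() else str(config)
        loaded = yaml.safe_load(text)
        if loaded is None:
            doc = {}
        elif isinstance(loaded, Mapping):
            doc = loaded
        else:
            raise ConfigError("configuration document must be a mapping")
    merged = _deep_merge(defaults, doc)

    ring = OrientationRing(_require(merged["ring"], "n_orientations", int, "ring"))

    pops: dict[str, int] = {}
    pop_section = merged["populations"]
    for layer in LAYERS:
        if layer not in pop_section:
            raise ConfigError(f"missing configuration key: populations.{layer}")
        for ct in CELL_TYPES:
            n = _require(pop_section[layer], ct, int, f"populations.{layer}")
            if n < 1:
                raise SpecValidationError(f"populations.{layer}.{ct} must be >= 1")
            pops[f"{layer}{ct}"] = n

    connectivity = ConnectivityTables(merged["connectivity"])

    nsec = merged["neuron"]
    neuron = NeuronParams(
        tau_m_ms=_require(nsec, "tau_m_ms", float, "neuron"),
        c_m_pf=_require(nsec, "c_m_pf", float, "neuron"),
        e_l_mv=_require(nsec, "e_l_mv", float, "neuron"),
        v_th_mv=_require(nsec, "v_th_mv", float, "neuron"),
        v_reset_mv=_require(nsec, "v_reset_mv", float, "neuron"),
        t_ref_ms=_require(nsec, "t_ref_ms", float, "neuron"),
        tau_syn_ms=_require(nsec, "tau_syn_ms", float, "neuron"),
    )

    ssec = merged["synapse"]
    synapse = SynapseSpec(
        w_exc_pa=_require(ssec, "w_exc_pa", float, "synapse"),
        g=_require(ssec, "g", float, "synapse"),
        intra_mc_weight_scale=_require(ssec, "intra_mc_weight_scale", float, "synapse"),
        w_input_pa=_require(ssec, "w_input_pa", float, "synapse"),
        delay_exc_mean_ms=_require(ssec, "delay_exc_mean_ms", float, "synapse"),
        delay_exc_sd_ms=_require(ssec, "delay_exc_sd_ms", float, "synapse"),
        delay_inh_mean_ms=_require(ssec, "delay_inh_mean_ms", float, "synapse"),
        delay_inh_sd_ms=_require(ssec, "delay_inh_sd_ms", float, "synapse"),
    )

    isec = merged["inter_mc"]
    inter_mc = InterMcSpec(
        p_lateral_inhibition=_require(isec, "p_lateral_inhibition", float, "inter_mc"),
        p_similar_excitation=_require(isec, "p_similar_excitation", float, "inter_mc"),
        similar_max_ring_distance=_require(
            isec, "similar_max_ring_distance", int, "inter_mc"
        ),
        enable_exc_exc=_require(isec, "enable_exc_exc", bool, "inter_mc"),
    )

    bsec = merged["background"]
    background = BackgroundSpec(
        rates_hz={
            pop: _require(bsec["rates_hz"], pop, float, "background.rates_hz")
            for pop in POPULATIONS
        },
        fibers={
            pop: _require(bsec["fibers"], pop, int, "background.fibers")
            for pop in POPULATIONS
        },
    )

    scale = merged["scale"]
    k = _require(scale, "k", float, "scale")
    if not 0.0 < k <= 1.0:
        raise SpecValidationError(f"scale.k={k} outside (0, 1]")

    for key, p in merged["stimulus"]["projection"].items():
        if not 0.0 <= p <= 1.0:
            raise SpecValidationError(f"stimulus.projection.{key}={p} outside [0, 1]")
    for key, p in merged["attention"]["projection"].items():
        if not 0.0 <= p <= 1.0:
            raise SpecValidationError(f"attention.projection.{key}={p} outside [0, 1]")

    return ModelSpec(
        ring=ring,
        reference_populations=pops,
        connectivity=connectivity,
        neuron=neuron,
        synapse=synapse,
        inter_mc=inter_mc,
        background=background,
        stimulus=copy.deepcopy(merged["stimulus"]),
        attention=copy.deepcopy(merged["attention"]),
        noise=copy.deepcopy(merged["noise"]),
        simulation=copy.deepcopy(merged["simulation"]),
        scale_k=k,
        weight_compensation_exponent=_require(
            scale, "weight_compensation_exponent", float, "scale"
        ),
        master_seed=int(merged.get("master_seed", 0)),
    )


def scale_spec(spec: ModelSpec, k: float) -> ModelSpec:
    """Return a copy of ``spec`` at scale ``k`` relative to the reference.

    Population sizes become round(k * N_ref) (at least 1) and all recurrent
    weights are multiplied by (1/k)**exponent so the expected summed input per
    neuron is preserved.  External fiber counts and weights are unchanged.
    """
    if not isinstance(k, (int, float)) or isinstance(k, bool):
        raise TypeError("k must be a number")
    if not 0.0 < k <= 1.0:
        raise ValueError(f"scale factor k={k} outside (0, 1]")
    out = copy.deepcopy(spec)
    out.scale_k = float(k)
    return out


def expected_indegree(c: float, n_pre: int) -> float:
    """Expected synapses per postsynaptic neuron for pairwise probability c."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"connection probability {c} outside [0, 1]")
    if n_pre < 0:
        raise ValueError("n_pre must be >= 0")
    return c * n_pre
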