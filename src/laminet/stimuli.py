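"""Bottom-up oriented-bar drive, top-down attention, and external noise.

A bar of orientation theta drives each microcircuit's L4 and L6 through a
Poisson fiber bundle whose rate falls off with the circular distance between
the bar and the microcircuit's preferred orientation (peak 20 Hz at the
preferred one).  Top-down attention is a weak (5 Hz) bundle into L2/3 and L5:
the *spatial* mode targets all eight microcircuits identically, the *feature*
mode only the microcircuit preferring the attended orientation.  External
noise reuses the bottom-up pathway at a flat rate into every microcircuit
except the one preferring the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ModelSpec
from .engine import InputEnsemble
from .network import Network, _substream_seed

ATTENTION_MODES = ("neutral", "spatial", "feature")


@dataclass(frozen=True)
class StimulusSpec:
    """A single oriented-bar stimulus and its projection pathway."""

    orientation_deg: float
    peak_rate_hz: float = 20.0
    n_fibers: int = 225
    tuning_width_deg: float = 30.0
    floor_rate_hz: float = 0.0
    projection: dict | None = None  # {L4e, L4i, L6e, L6i: probability}

    @classmethod
    def from_model(cls, spec: ModelSpec, orientation_deg: float) -> "StimulusSpec":
        s = spec.stimulus
        return cls(
            orientation_deg=orientation_deg,
            peak_rate_hz=s["peak_rate_hz"],
            n_fibers=s["n_fibers"],
            tuning_width_deg=s["tuning_width_deg"],
            floor_rate_hz=s["floor_rate_hz"],
            projection=dict(s["projection"]),
        )


@dataclass(frozen=True)
class AttentionSpec:
    """Top-down attention mode and its projection pathway."""

    mode: str                       # neutral | spatial | feature
    attended_orientation_deg: float | None = None
    rate_hz: float = 5.0
    n_fibers_per_layer: int = 300
    projection: dict | None = None  # {L23e, L23i, L5e, L5i: probability}

    def __post_init__(self) -> None:
        if self.mode not in ATTENTION_MODES:
            raise ValueError(f"unknown attention mode {self.mode!r}")
        if self.mode == "feature" and self.attended_orientation_deg is None:
            raise ValueError("feature-based attention requires an attended orientation")

    @classmethod
    def from_model(
        cls, spec: ModelSpec, mode: str, attended_orientation_deg: float | None = None
    ) -> "AttentionSpec":
        a = spec.attention
        return cls(
            mode=mode,
            attended_orientation_deg=attended_orientation_deg,
            rate_hz=a["rate_hz"],
            n_fibers_per_layer=a["n_fibers_per_layer"],
            projection=dict(a["projection"]),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Orientation-unrelated external noise on the bottom-up pathway."""

    rate_hz: float
    n_fibers: int = 225

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("noise rate must be >= 0")


def input_rate_for_orientation(
    stim_theta_deg: float, mc_theta_deg: float, stim: StimulusSpec
) -> float:
    """Fiber rate (Hz) a microcircuit receives for a bar of given orientation.

    Circular Gaussian on the 180-degree-periodic orientation distance:
    peak rate at zero distance, symmetric, strictly decreasing to 90 degrees.
    """
    d = abs(stim_theta_deg - mc_theta_deg) % 180.0
    d = min(d, 180.0 - d)
    rate = stim.peak_rate_hz * np.exp(-(d**2) / (2.0 * stim.tuning_width_deg**2))
    return float(max(rate, stim.floor_rate_hz))


def _bottom_up_groups(net: Network, mc: int, projection: dict):
    return [
        (net.pop_gids(mc, "L4e"), projection["L4e"]),
        (net.pop_gids(mc, "L4i"), projection["L4i"]),
        (net.pop_gids(mc, "L6e"), projection["L6e"]),
        (net.pop_gids(mc, "L6i"), projection["L6i"]),
    ]


def make_bottom_up(
    orientations_deg: Sequence[float],
    spec: ModelSpec,
    net: Network,
    seed: int,
) -> list[InputEnsemble]:
    """Fiber ensembles for one or two simultaneous bars (superposed)."""
    orientations = list(orientations_deg)
    if len(orientations) == 0:
        return []
    if len(orientations) > 2:
        raise ValueError("at most 2 simultaneous stimuli are supported")
    out = []
    for si, theta in enumerate(orientations):
        stim = StimulusSpec.from_model(spec, theta)
        for mc, pref in enumerate(spec.ring.preferred_orientations):
            rate = input_rate_for_orientation(theta, pref, stim)
            if rate <= 0:
                continue
            out.append(
                InputEnsemble.from_projection(
                    label=f"stimulus{si}:{theta:g}deg:mc{mc}",
                    rate_hz=rate,
                    n_fibers=stim.n_fibers,
                    weight_pa=spec.input_weight_pa,
                    target_groups=_bottom_up_groups(net, mc, stim.projection),
                    seed=_substream_seed(seed, 31, si, mc),
                )
            )
    return out


def make_top_down(
    attention: AttentionSpec,
    spec: ModelSpec,
    net: Network,
    seed: int,
) -> list[InputEnsemble]:
    """Top-down ensembles: none (neutral), all mcs (spatial), one (feature)."""
    if attention.mode == "neutral":
        return []
    if attention.mode == "spatial":
        mcs = list(range(spec.ring.n))
    else:
        mcs = [spec.ring.index_of(attention.attended_orientation_deg)]
    proj = attention.projection
    out = []
    for mc in mcs:
        for li, (layer, groups) in enumerate(
            (
                ("L23", [(net.pop_gids(mc, "L23e"), proj["L23e"]),
                         (net.pop_gids(mc, "L23i"), proj["L23i"])]),
                ("L5", [(net.pop_gids(mc, "L5e"), proj["L5e"]),
                        (net.pop_gids(mc, "L5i"), proj["L5i"])]),
            )
        ):
            out.append(
                InputEnsemble.from_projection(
                    label=f"attention:{attention.mode}:mc{mc}:{layer}",
                    rate_hz=attention.rate_hz,
                    n_fibers=attention.n_fibers_per_layer,
                    weight_pa=spec.input_weight_pa,
                    target_groups=groups,
                    seed=_substream_seed(seed, 41, mc, li),
                )
            )
    return out


def make_noise(
    noise: NoiseSpec,
    stimulus_orientation_deg: float,
    spec: ModelSpec,
    net: Network,
    seed: int,
) -> list[InputEnsemble]:
    """Flat-rate bottom-up noise into every non-stimulus microcircuit."""
    if noise.rate_hz == 0:
        return []
    stim_mc = spec.ring.index_of(stimulus_orientation_deg)
    projection = dict(spec.stimulus["projection"])
    out = []
    for mc in range(spec.ring.n):
        if mc == stim_mc:
            continue
        out.append(
            InputEnsemble.from_projection(
                label=f"noise:mc{mc}",
                rate_hz=noise.rate_hz,
                n_fibers=noise.n_fibers,
                weight_pa=spec.input_weight_pa,
                target_groups=_bottom_up_groups(net, mc, projection),
                seed=_substream_seed(seed, 51, mc),
            )
        )
    return out
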