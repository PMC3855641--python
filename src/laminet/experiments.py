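"""Scenario runner: the model's experiments end-to-end at configurable scale.

A scenario is a list of input conditions (stimuli, attention mode, noise)
run for a number of trials on one fixed network realization; trials differ
in the Poisson input realization.  Statistics relevant to the scenario
(population rates, tuning fits and their tests, attention indices, d')
are computed from the spikes and returned as tidy tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .config import LAYERS, POPULATIONS, ModelSpec, load_model_spec, scale_spec
from .engine import attach_background, simulate
from .network import Network, _substream_seed, build_network
from .stimuli import AttentionSpec, NoiseSpec, make_bottom_up, make_noise, make_top_down

SCENARIO_NAMES = (
    "spontaneous",
    "tuning_neutral",
    "tuning_spatial",
    "tuning_feature",
    "biased_competition",
    "noise_sweep_coarse",
    "noise_sweep_fine",
)


@dataclass(frozen=True)
class Condition:
    """One fully resolved input configuration."""

    label: str
    stimuli: tuple[float, ...] = ()
    attention_mode: str = "neutral"
    attended_deg: float | None = None
    noise_hz: float = 0.0


@dataclass(frozen=True)
class Scenario:
    name: str
    conditions: tuple[Condition, ...]
    n_trials: int
    compute_tuning: bool = False
    compute_ai: bool = False
    dprime_comparison_mc: int | None = None
    readout_mc: int = 0


def make_scenario(name: str, n_trials: int | None = None) -> Scenario:
    """Resolve a named experiment into its input conditions.

    Reference trial counts: 50 for tuning/AI scenarios, 5 for biased
    competition; pass ``n_trials`` to scale down.
    """
    neutral = Condition("neutral", stimuli=(0.0,))
    spatial = Condition("spatial", stimuli=(0.0,), attention_mode="spatial")
    feature = Condition(
        "feature", stimuli=(0.0,), attention_mode="feature", attended_deg=0.0
    )
    if name == "spontaneous":
        return Scenario(name, (Condition("spontaneous"),), n_trials or 3)
    if name == "tuning_neutral":
        return Scenario(name, (neutral,), n_trials or 50, compute_tuning=True)
    if name == "tuning_spatial":
        return Scenario(
            name, (neutral, spatial), n_trials or 50,
            compute_tuning=True, compute_ai=True,
        )
    if name == "tuning_feature":
        return Scenario(
            name, (neutral, feature), n_trials or 50,
            compute_tuning=True, compute_ai=True,
        )
    if name == "biased_competition":
        conds = (
            Condition("pref_only", stimuli=(0.0,)),
            Condition("orth_only", stimuli=(90.0,)),
            Condition("pair", stimuli=(0.0, 90.0)),
            Condition("pair_attend_pref", stimuli=(0.0, 90.0),
                      attention_mode="feature", attended_deg=0.0),
            Condition("pair_attend_orth", stimuli=(0.0, 90.0),
                      attention_mode="feature", attended_deg=90.0),
        )
        return Scenario(name, conds, n_trials or 5)
    if name in ("noise_sweep_coarse", "noise_sweep_fine"):
        conds = []
        for level in (2.5, 5.0, 10.0, 15.0):
            for base in (neutral, spatial, feature):
                conds.append(replace(base, label=f"{base.label}", noise_hz=level))
        comparison = 4 if name == "noise_sweep_coarse" else 1
        return Scenario(
            name, tuple(conds), n_trials or 50, dprime_comparison_mc=comparison
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


@dataclass
class ResultsBundle:
    """Tidy result tables of one scenario run."""

    scenario: Scenario
    spec_hash: str
    seed: int
    rates: pd.DataFrame
    tuning: pd.DataFrame | None = None
    tuning_tests: pd.DataFrame | None = None
    ai: pd.DataFrame | None = None
    ai_summary: pd.DataFrame | None = None
    dprime: pd.DataFrame | None = None
    spikes: dict = field(default_factory=dict, repr=False)

    def save(self, out_dir: str | Path, spec: ModelSpec | None = None,
             overwrite: bool = False) -> Path:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"{out} is not empty; pass overwrite to replace")
        out.mkdir(parents=True, exist_ok=True)
        (out / "provenance.txt").write_text(
            f"scenario={self.scenario.name}\nseed={self.seed}\n"
            f"spec_hash={self.spec_hash}\nn_trials={self.scenario.n_trials}\n"
        )
        if spec is not None:
            (out / "config_snapshot.yaml").write_text(spec.to_yaml())
        for name in ("rates", "tuning", "tuning_tests", "ai", "ai_summary", "dprime"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        for label, spk in self.spikes.items():
            spk.save(out / f"spikes_{label}.tsv")
        return out


def _condition_inputs(cond: Condition, spec: ModelSpec, net: Network, wiring_seed: int):
    """Realize all fiber ensembles of a condition (wiring is seed-fixed)."""
    inputs = attach_background(net, spec)
    if cond.stimuli:
        inputs += make_bottom_up(cond.stimuli, spec, net, wiring_seed)
    att = AttentionSpec.from_model(spec, cond.attention_mode, cond.attended_deg)
    inputs += make_top_down(att, spec, net, wiring_seed)
    if cond.noise_hz > 0 and cond.stimuli:
        noise = NoiseSpec(cond.noise_hz, spec.noise["n_fibers"])
        inputs += make_noise(noise, cond.stimuli[0], spec, net, wiring_seed)
    return inputs


def run_scenario(
    scenario: Scenario | str,
    spec: ModelSpec | None = None,
    seed: int = 0,
    backend: str = "numba",
    keep_spikes: bool = False,
) -> ResultsBundle:
    """Run all conditions x trials of a scenario and compute its statistics."""
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    if spec is None:
        spec = load_model_spec(None)

    warmup = float(spec.simulation["warmup_ms"])
    record = float(spec.simulation["record_ms"])
    dt = float(spec.simulation["dt_ms"])
    window = (warmup, warmup + record)
    duration = warmup + record

    net = build_network(spec, _substream_seed(seed, 101))
    wiring_seed = _substream_seed(seed, 102)

    mc0 = scenario.readout_mc
    ai_pops = {
        "e": np.concatenate([net.pop_gids(mc0, "L23e"), net.pop_gids(mc0, "L5e")]),
        "i": np.concatenate([net.pop_gids(mc0, "L23i"), net.pop_gids(mc0, "L5i")]),
    }

    rate_rows = []
    neuron_rates: dict[str, dict[str, list[np.ndarray]]] = {}
    spikes_kept: dict = {}
    for ci, cond in enumerate(scenario.conditions):
        inputs = _condition_inputs(cond, spec, net, wiring_seed)
        neuron_rates[cond.label] = {"e": [], "i": []}
        for trial in range(scenario.n_trials):
            run_seed = _substream_seed(seed, 103, ci, trial)
            spk = simulate(
                net, inputs, duration_ms=duration, dt_ms=dt,
                seed=run_seed, backend=backend, neuron=spec.neuron,
            )
            for mc in range(net.n_mc):
                for pop in POPULATIONS:
                    r = analysis.population_rate(spk, net.pop_gids(mc, pop), window)
                    rate_rows.append(
                        {
                            "condition": cond.label,
                            "noise_hz": cond.noise_hz,
                            "trial": trial,
                            "mc": mc,
                            "layer": pop[:-1],
                            "cell_type": pop[-1],
                            "rate_hz": r,
                        }
                    )
            if scenario.compute_ai:
                for ct in ("e", "i"):
                    neuron_rates[cond.label][ct].append(
                        analysis.per_neuron_rates(spk, ai_pops[ct], window)
                    )
            if keep_spikes:
                spikes_kept[f"{cond.label}_t{trial}"] = spk
    rates = pd.DataFrame(rate_rows)

    bundle = ResultsBundle(
        scenario=scenario,
        spec_hash=spec.spec_hash(),
        seed=int(seed),
        rates=rates,
        spikes=spikes_kept,
    )
    if scenario.compute_tuning:
        bundle.tuning, bundle.tuning_tests = _tuning_stats(scenario, spec, rates)
    if scenario.compute_ai:
        bundle.ai, bundle.ai_summary = _ai_stats(scenario, ai_pops, neuron_rates, seed)
    if scenario.dprime_comparison_mc is not None:
        bundle.dprime = _dprime_stats(scenario, rates)
    return bundle


def _tuning_stats(scenario: Scenario, spec: ModelSpec, rates: pd.DataFrame):
    """Per-trial Gaussian tuning fits for L2/3e and L5e, plus t-tests."""
    orientations = np.asarray(spec.ring.preferred_orientations)
    fit_rows = []
    fits: dict[tuple[str, str], list[analysis.TuningFit]] = {}
    for cond in scenario.conditions:
        stim_deg = cond.stimuli[0] if cond.stimuli else 0.0
        for layer in ("L23", "L5"):
            sub = rates[
                (rates.condition == cond.label)
                & (rates.layer == layer)
                & (rates.cell_type == "e")
            ]
            per_trial = sub.pivot_table(index="trial", columns="mc", values="rate_hz")
            fits[(cond.label, layer)] = []
            for trial, row in per_trial.iterrows():
                fit = analysis.fit_orientation_tuning(
                    orientations, row.to_numpy(), stim_deg
                )
                fits[(cond.label, layer)].append(fit)
                fit_rows.append(
                    {
                        "condition": cond.label,
                        "layer": layer,
                        "trial": trial,
                        "baseline_hz": fit.baseline_hz,
                        "amplitude_hz": fit.amplitude_hz,
                        "mu_deg": fit.mu_deg,
                        "sigma_deg": fit.sigma_deg,
                        "residual_ss": fit.residual_ss,
                    }
                )
    tuning = pd.DataFrame(fit_rows)

    test_rows = []
    labels = [c.label for c in scenario.conditions]
    if "neutral" in labels:
        for cond in scenario.conditions:
            if cond.label == "neutral":
                continue
            for layer in ("L23", "L5"):
                res = analysis.compare_tuning_params(
                    fits[(cond.label, layer)], fits[("neutral", layer)]
                )
                for param, tr in res.items():
                    test_rows.append(
                        {
                            "condition": cond.label,
                            "layer": layer,
                            "parameter": param,
                            "statistic": tr.statistic,
                            "p_value": tr.p_value,
                            "test": tr.test_name,
                        }
                    )
                mw = analysis.peak_location_test(
                    np.abs([f.mu_deg for f in fits[(cond.label, layer)]]),
                    np.abs([f.mu_deg for f in fits[("neutral", layer)]]),
                )
                test_rows.append(
                    {
                        "condition": cond.label,
                        "layer": layer,
                        "parameter": "peak_location",
                        "statistic": mw.statistic,
                        "p_value": mw.p_value,
                        "test": mw.test_name,
                    }
                )
    tests = pd.DataFrame(test_rows) if test_rows else None
    return tuning, tests


def _ai_stats(scenario: Scenario, ai_pops, neuron_rates, seed: int):
    """Attention indices of the readout microcircuit's L2/3 + L5 neurons."""
    attended_label = next(
        (c.label for c in scenario.conditions if c.attention_mode != "neutral"), None
    )
    if attended_label is None or "neutral" not in neuron_rates:
        return None, None
    ai_rows = []
    summary_rows = []
    counts = {}
    for ct in ("e", "i"):
        att = np.stack(neuron_rates[attended_label][ct])
        neu = np.stack(neuron_rates["neutral"][ct])
        records = analysis.build_ai_records(ai_pops[ct], att, neu)
        for r in records:
            ai_rows.append(
                {
                    "condition": attended_label,
                    "cell_type": ct,
                    "gid": r.gid,
                    "attended_hz": r.attended_hz,
                    "unattended_hz": r.unattended_hz,
                    "ai": r.ai,
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "sign": r.sign,
                }
            )
        finite = [r.ai for r in records if np.isfinite(r.ai)]
        n_sig = sum(r.significant for r in records)
        n_pos = sum(r.significant and r.sign > 0 for r in records)
        counts[ct] = (n_sig, n_pos)
        summary_rows.append(
            {
                "condition": attended_label,
                "cell_type": ct,
                "n_neurons": len(records),
                "median_ai": float(np.median(finite)) if finite else np.nan,
                "n_significant": n_sig,
                "n_positive": n_pos,
                "prop_positive": n_pos / n_sig if n_sig else np.nan,
            }
        )
    summary = pd.DataFrame(summary_rows)
    if counts["e"][0] >= 1 and counts["i"][0] >= 1:
        boot = analysis.bootstrap_proportion_test(
            counts["e"], counts["i"], seed=_substream_seed(seed, 104)
        )
        summary["bootstrap_p"] = boot.p_value
    return pd.DataFrame(ai_rows), summary


def _dprime_stats(scenario: Scenario, rates: pd.DataFrame):
    """d' per condition and noise level for L2/3 and L5 excitatory pools.

    The non-preferred-response distribution is read, by ring symmetry, from
    the comparison microcircuit's response to the same (vertical) bar.
    """
    mc_pref = scenario.readout_mc
    mc_cmp = scenario.dprime_comparison_mc
    rows = []
    for (label, noise), sub in rates[rates.cell_type == "e"].groupby(
        ["condition", "noise_hz"]
    ):
        for layer in ("L23", "L5"):
            pref = sub[(sub.mc == mc_pref) & (sub.layer == layer)].sort_values("trial")
            comp = sub[(sub.mc == mc_cmp) & (sub.layer == layer)].sort_values("trial")
            ds = analysis.discriminability_from_trials(
                pref.rate_hz.to_numpy(), comp.rate_hz.to_numpy()
            )
            rows.append(
                {
                    "condition": label,
                    "noise_hz": noise,
                    "layer": layer,
                    "mean_pref_hz": ds.mean_pref_hz,
                    "sd_pref_hz": ds.sd_pref_hz,
                    "mean_nonpref_hz": ds.mean_nonpref_hz,
                    "sd_nonpref_hz": ds.sd_nonpref_hz,
                    "d_prime": ds.d_prime,
                }
            )
    return pd.DataFrame(rows)


def make_fixture_network(n_per_population: int = 10, seed: int = 0):
    """Miniature 8-microcircuit network with every pathway type, for tests."""
    if n_per_population < 1:
        raise ValueError("n_per_population must be >= 1")
    pops = {
        layer: {"e": n_per_population, "i": n_per_population} for layer in LAYERS
    }
    spec = load_model_spec({"populations": pops})
    net = build_network(spec, seed)
    return spec, net


def desk_spec(k: float = 0.125, record_ms: float | None = None,
              config: dict | None = None) -> ModelSpec:
    """Reference spec scaled down for interactive / desk-size runs."""
    spec = load_model_spec(config)
    spec = scale_spec(spec, k)
    if record_ms is not None:
        spec.simulation["record_ms"] = float(record_ms)
    return spec
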