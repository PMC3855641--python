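"""Statistics computed from spike data.

Population rates, 4-parameter Gaussian orientation-tuning fits and their
trial-wise comparisons, per-neuron attention indices with significance
classification, a bootstrap comparison of modulation sign between cell
types, and the signal-detection discriminability d'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .engine import SpikeData


@dataclass(frozen=True)
class TuningFit:
    """r(theta) = baseline + amplitude * exp(-(theta-mu)^2 / (2 sigma^2))."""

    baseline_hz: float
    amplitude_hz: float
    mu_deg: float        # peak location on the centered (-90, +90] domain
    sigma_deg: float     # tuning width (SD)
    residual_ss: float

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        theta_deg = np.asarray(theta_deg, dtype=float)
        return self.baseline_hz + self.amplitude_hz * np.exp(
            -((theta_deg - self.mu_deg) ** 2) / (2.0 * self.sigma_deg**2)
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str      # "t" | "mann-whitney" | "bootstrap"
    n: int


@dataclass(frozen=True)
class AIRecord:
    """Per-neuron attention statistics (attended vs unattended rates)."""

    gid: int
    attended_hz: float
    unattended_hz: float
    ai: float            # nan when both rates are zero
    p_value: float
    significant: bool
    sign: int            # +1 / -1 from the mean rate difference

    @property
    def modulation_ratio(self) -> float:
        if not np.isfinite(self.ai) or self.ai >= 1.0:
            return np.inf
        return (1.0 + self.ai) / (1.0 - self.ai)


@dataclass(frozen=True)
class DiscriminabilityStats:
    mean_pref_hz: float
    sd_pref_hz: float
    mean_nonpref_hz: float
    sd_nonpref_hz: float
    d_prime: float


# ---------------------------------------------------------------------------
# rates


def population_rate(
    spikes: SpikeData, gids: np.ndarray, window_ms: tuple[float, float]
) -> float:
    """Mean firing rate (Hz) of a neuron set within a time window."""
    gids = np.asarray(gids)
    if gids.size == 0:
        raise ValueError("population selector is empty")
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window must have positive length")
    n_spikes = int(spikes.counts(gids, t0, t1).sum())
    return n_spikes / (gids.size * (t1 - t0) / 1000.0)


def per_neuron_rates(
    spikes: SpikeData, gids: np.ndarray, window_ms: tuple[float, float]
) -> np.ndarray:
    """Firing rate (Hz) of each listed neuron within a time window."""
    t0, t1 = window_ms
    return spikes.counts(np.asarray(gids), t0, t1) / ((t1 - t0) / 1000.0)


# ---------------------------------------------------------------------------
# tuning curves


def center_orientations(
    orientations_deg: np.ndarray, stimulus_deg: float
) -> np.ndarray:
    """Re-center orientations to the (-90, +90] interval around a stimulus."""
    d = (np.asarray(orientations_deg, dtype=float) - stimulus_deg) % 180.0
    return np.where(d > 90.0, d - 180.0, d)


def fit_orientation_tuning(
    orientations_deg: np.ndarray,
    rates_hz: np.ndarray,
    stimulus_deg: float = 0.0,
) -> TuningFit:
    """Least-squares Gaussian tuning fit on the centered orientation domain.

    Multi-start bounded nonlinear least squares (restarts over mu and sigma,
    deterministic order); bounds: baseline >= 0, amplitude free,
    sigma in (0, 90], mu in [-90, 90].
    """
    theta = center_orientations(orientations_deg, stimulus_deg)
    rates = np.asarray(rates_hz, dtype=float)
    if np.unique(theta).size < 5 or not np.all(np.isfinite(rates)):
        raise ValueError("need >= 5 distinct orientations with finite rates")

    order = np.argsort(theta)
    theta, rates = theta[order], rates[order]
    rmin, rmax = float(rates.min()), float(rates.max())
    amp0 = max(rmax - rmin, 1e-3)

    def residual(p):
        b, a, mu, sigma = p
        return b + a * np.exp(-((theta - mu) ** 2) / (2.0 * sigma**2)) - rates

    lb = [0.0, -np.inf, -90.0, 1e-6]
    ub = [np.inf, np.inf, 90.0, 90.0]
    best = None
    starts = [
        (max(rmin, 0.0), amp0, mu0, s0)
        for mu0 in (-45.0, 0.0, 45.0)
        for s0 in (15.0, 30.0)
    ]
    for p0 in starts:
        try:
            sol = optimize.least_squares(residual, p0, bounds=(lb, ub))
        except Exception:
            continue
        if sol.success or sol.status > 0:
            ss = float(np.sum(sol.fun**2))
            if best is None or ss < best[0] - 1e-12:
                best = (ss, sol.x)
    if best is None:
        raise RuntimeError(
            f"tuning fit failed to converge (orientations={theta.tolist()}, "
            f"rates={rates.tolist()})"
        )
    ss, (b, a, mu, sigma) = best
    return TuningFit(
        baseline_hz=float(b),
        amplitude_hz=float(a),
        mu_deg=float(mu),
        sigma_deg=float(sigma),
        residual_ss=ss,
    )


def _ttest(a: np.ndarray, b: np.ndarray) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, "t", a.size + b.size)
        return TestResult(np.inf * np.sign(a.mean() - b.mean()), 0.0, "t",
                          a.size + b.size)
    t, p = stats.ttest_ind(a, b)
    if np.isnan(p):
        p = 1.0
    return TestResult(float(t), float(p), "t", a.size + b.size)


def compare_tuning_params(
    fits_a: list[TuningFit], fits_b: list[TuningFit]
) -> dict[str, TestResult]:
    """Two-sample t-tests on baseline, amplitude and width across trials."""
    if len(fits_a) != len(fits_b) or len(fits_a) < 2:
        raise ValueError("need equal trial counts >= 2")
    out = {}
    for name, attr in (
        ("baseline", "baseline_hz"),
        ("amplitude", "amplitude_hz"),
        ("width", "sigma_deg"),
    ):
        a = np.array([getattr(f, attr) for f in fits_a])
        b = np.array([getattr(f, attr) for f in fits_b])
        out[name] = _ttest(a, b)
    return out


def peak_location_test(abs_mu_a: np.ndarray, abs_mu_b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U on absolute tuning-peak locations."""
    a = np.asarray(abs_mu_a, dtype=float)
    b = np.asarray(abs_mu_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        u = a.size * b.size / 2.0
        return TestResult(float(u), 1.0, "mann-whitney", a.size + b.size)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(float(u), float(p), "mann-whitney", a.size + b.size)


# ---------------------------------------------------------------------------
# attention indices


def attention_index(attended_hz: float, unattended_hz: float) -> float:
    """(A - U) / (A + U); nan when both rates are zero (undefined)."""
    if attended_hz < 0 or unattended_hz < 0:
        raise ValueError("rates must be >= 0")
    s = attended_hz + unattended_hz
    if s == 0:
        return np.nan
    return (attended_hz - unattended_hz) / s


def modulation_ratio(ai: float) -> float:
    """(1 + AI) / (1 - AI); equals A/U for U > 0."""
    if not np.isfinite(ai):
        return np.nan
    if ai >= 1.0:
        return np.inf
    return (1.0 + ai) / (1.0 - ai)


def classify_modulation(
    attended_trial_rates: np.ndarray,
    neutral_trial_rates: np.ndarray,
    alpha: float = 0.05,
) -> tuple[bool, int, float]:
    """Per-neuron attention significance: (significant, sign, p_value).

    Two-sample t-test across trials; two all-zero conditions are not
    significant by convention.
    """
    a = np.asarray(attended_trial_rates, dtype=float)
    u = np.asarray(neutral_trial_rates, dtype=float)
    if a.size < 2 or u.size < 2:
        raise ValueError("need >= 2 trials per condition")
    if not a.any() and not u.any():
        return False, 0, 1.0
    res = _ttest(a, u)
    sign = 1 if a.mean() >= u.mean() else -1
    return bool(res.p_value < alpha), sign, res.p_value


def build_ai_records(
    gids: np.ndarray,
    attended_rates: np.ndarray,   # (n_trials, n_neurons)
    neutral_rates: np.ndarray,
    alpha: float = 0.05,
) -> list[AIRecord]:
    """AI + significance classification for every neuron of a population."""
    attended_rates = np.asarray(attended_rates, dtype=float)
    neutral_rates = np.asarray(neutral_rates, dtype=float)
    records = []
    for j, gid in enumerate(np.asarray(gids)):
        a_mean = float(attended_rates[:, j].mean())
        u_mean = float(neutral_rates[:, j].mean())
        ai = attention_index(a_mean, u_mean)
        sig, sign, p = classify_modulation(
            attended_rates[:, j], neutral_rates[:, j], alpha
        )
        records.append(
            AIRecord(
                gid=int(gid),
                attended_hz=a_mean,
                unattended_hz=u_mean,
                ai=ai,
                p_value=p,
                significant=sig,
                sign=sign,
            )
        )
    return records


def bootstrap_proportion_test(
    exc_counts: tuple[int, int],
    inh_counts: tuple[int, int],
    n_resamples: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Bootstrap comparison of positive-modulation proportions by cell type.

    ``(n_significant, n_positive)`` per cell type; significantly modulated
    neurons are resampled with replacement within each type and the p-value
    is the two-sided tail fraction of the resampled proportion difference
    around zero.
    """
    (n_e, pos_e), (n_i, pos_i) = exc_counts, inh_counts
    if n_e < 1 or n_i < 1:
        raise ValueError("need at least one significant neuron per cell type")
    rng = np.random.default_rng(seed)
    pe = rng.binomial(n_e, pos_e / n_e, size=n_resamples) / n_e
    pi = rng.binomial(n_i, pos_i / n_i, size=n_resamples) / n_i
    diff = pe - pi
    observed = pos_e / n_e - pos_i / n_i
    lower = float(np.mean(diff >= 0.0))
    upper = float(np.mean(diff <= 0.0))
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(float(observed), p, "bootstrap", n_e + n_i)


# ---------------------------------------------------------------------------
# discriminability


def discriminability(
    mean_pref_hz: float,
    sd_pref_hz: float,
    mean_nonpref_hz: float,
    sd_nonpref_hz: float,
    denominator: str = "rms",
) -> DiscriminabilityStats:
    """Signal-detection d' between two trial-rate distributions.

    ``denominator="rms"`` (default) pools the SDs as sqrt((s1^2 + s2^2) / 2);
    ``"mean"`` uses their simple average.
    """
    if sd_pref_hz < 0 or sd_nonpref_hz < 0:
        raise ValueError("SDs must be >= 0")
    if sd_pref_hz == 0 and sd_nonpref_hz == 0:
        d = np.inf * np.sign(mean_pref_hz - mean_nonpref_hz) if (
            mean_pref_hz != mean_nonpref_hz
        ) else 0.0
    else:
        if denominator == "rms":
            pooled = np.sqrt((sd_pref_hz**2 + sd_nonpref_hz**2) / 2.0)
        elif denominator == "mean":
            pooled = (sd_pref_hz + sd_nonpref_hz) / 2.0
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        d = (mean_pref_hz - mean_nonpref_hz) / pooled
    return DiscriminabilityStats(
        mean_pref_hz=float(mean_pref_hz),
        sd_pref_hz=float(sd_pref_hz),
        mean_nonpref_hz=float(mean_nonpref_hz),
        sd_nonpref_hz=float(sd_nonpref_hz),
        d_prime=float(d),
    )


def discriminability_from_trials(
    pref_trial_rates: np.ndarray,
    nonpref_trial_rates: np.ndarray,
    denominator: str = "rms",
) -> DiscriminabilityStats:
    p = np.asarray(pref_trial_rates, dtype=float)
    q = np.asarray(nonpref_trial_rates, dtype=float)
    return discriminability(
        p.mean(), p.std(ddof=1), q.mean(), q.std(ddof=1), denominator
    )
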