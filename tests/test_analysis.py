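"""Statistics: rates, tuning fits, attention indices, tests, d-prime."""

import numpy as np
import pytest
from scipy import stats

from laminet import analysis
from laminet.analysis import (
    attention_index,
    bootstrap_proportion_test,
    classify_modulation,
    compare_tuning_params,
    discriminability,
    fit_orientation_tuning,
    modulation_ratio,
    peak_location_test,
    population_rate,
)
from laminet.engine import SpikeData

ORIENTATIONS = np.arange(8) * 22.5


def _spikes(gids, times, n_neurons, duration=1000.0):
    return SpikeData(
        gids=np.asarray(gids, np.int32),
        times_ms=np.asarray(times, float),
        duration_ms=duration,
        n_neurons=n_neurons,
        dt_ms=0.1,
    )


class TestPopulationRate:
    def test_no_spikes_is_zero(self):
        spk = _spikes([], [], 10)
        assert population_rate(spk, np.arange(10), (0.0, 1000.0)) == 0.0

    def test_simple_count(self):
        spk = _spikes(np.zeros(100), np.linspace(1, 999, 100), 10)
        assert population_rate(spk, np.arange(10), (0.0, 1000.0)) == pytest.approx(10.0)

    def test_matches_bruteforce_per_neuron_average(self):
        rng = np.random.default_rng(5)
        n, dur = 17, 800.0
        gids = rng.integers(0, n, 500)
        times = rng.uniform(0, dur, 500)
        spk = _spikes(gids, times, n, dur)
        window = (100.0, 700.0)
        brute = np.mean(
            [
                ((gids == i) & (times >= window[0]) & (times < window[1])).sum()
                / 0.6
                for i in range(n)
            ]
        )
        assert population_rate(spk, np.arange(n), window) == pytest.approx(brute)

    def test_empty_population_rejected(self):
        spk = _spikes([], [], 10)
        with pytest.raises(ValueError):
            population_rate(spk, np.array([]), (0.0, 100.0))


class TestTuningFit:
    def test_noiseless_recovery_is_exact(self):
        true = dict(b=1.0, a=8.0, mu=0.0, sigma=25.0)
        theta = analysis.center_orientations(ORIENTATIONS, 0.0)
        rates = true["b"] + true["a"] * np.exp(-(theta**2) / (2 * true["sigma"] ** 2))
        fit = fit_orientation_tuning(ORIENTATIONS, rates, 0.0)
        assert fit.baseline_hz == pytest.approx(true["b"], rel=1e-6, abs=1e-6)
        assert fit.amplitude_hz == pytest.approx(true["a"], rel=1e-6)
        assert fit.mu_deg == pytest.approx(true["mu"], abs=1e-5)
        assert fit.sigma_deg == pytest.approx(true["sigma"], rel=1e-6)

    def test_flat_rates_fit_as_baseline(self):
        fit = fit_orientation_tuning(ORIENTATIONS, np.full(8, 4.2), 0.0)
        assert abs(fit.amplitude_hz) < 1e-6
        assert fit.predict(np.array([0.0]))[0] == pytest.approx(4.2, abs=1e-6)

    def test_off_center_peak_recovered(self):
        theta = analysis.center_orientations(ORIENTATIONS, 0.0)
        rates = 2.0 + 6.0 * np.exp(-((theta - 20.0) ** 2) / (2 * 30.0**2))
        fit = fit_orientation_tuning(ORIENTATIONS, rates, 0.0)
        assert fit.mu_deg == pytest.approx(20.0, abs=1e-4)

    def test_too_few_orientations_rejected(self):
        with pytest.raises(ValueError):
            fit_orientation_tuning(ORIENTATIONS[:4], np.ones(4), 0.0)

    def test_noisy_recovery_unbiased_in_mu(self):
        """Mean recovered peak location within 2 deg of truth (sim oracle)."""
        rng = np.random.default_rng(42)
        theta = analysis.center_orientations(ORIENTATIONS, 0.0)
        clean = 1.0 + 8.0 * np.exp(-(theta**2) / (2 * 25.0**2))
        mus = []
        for _ in range(50):
            noisy = clean + rng.normal(0, 0.5, 8)
            mus.append(fit_orientation_tuning(ORIENTATIONS, noisy, 0.0).mu_deg)
        assert abs(np.mean(mus)) < 2.0


class TestParameterComparisons:
    def _fits(self, values, param="amplitude_hz"):
        out = []
        for v in values:
            kw = dict(baseline_hz=1.0, amplitude_hz=5.0, mu_deg=0.0,
                      sigma_deg=25.0, residual_ss=0.0)
            kw[param] = v
            out.append(analysis.TuningFit(**kw))
        return out

    def test_identical_samples_give_p_one(self):
        a = self._fits([5.0] * 10)
        res = compare_tuning_params(a, a)
        assert all(r.p_value == 1.0 for r in res.values())

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = self._fits(rng.normal(5, 0.1, 20))
        b = self._fits(rng.normal(6, 0.1, 20))
        assert compare_tuning_params(a, b)["amplitude"].p_value < 0.01

    def test_t_statistic_matches_textbook_formula(self):
        x = [4.1, 5.0, 5.5, 4.4, 5.2]
        y = [6.0, 6.4, 5.1, 6.8, 5.9]
        a, b = self._fits(x), self._fits(y)
        res = compare_tuning_params(a, b)["amplitude"]
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
            nx + ny - 2
        )
        t_hand = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)

    def test_mann_whitney_u_matches_pair_counting(self):
        a = np.array([1.0, 3.0, 5.0, 7.0])
        b = np.array([2.0, 4.0, 6.0])
        res = peak_location_test(a, b)
        u_brute = sum(
            (x > y) + 0.5 * (x == y) for x in a for y in b
        )
        assert res.statistic == pytest.approx(u_brute)

    def test_mann_whitney_disjoint_supports_significant(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 50)
        b = rng.uniform(2, 3, 50)
        assert peak_location_test(a, b).p_value < 0.01

    def test_mann_whitney_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        assert peak_location_test(a, a).p_value == 1.0


class TestAttentionIndex:
    @pytest.mark.parametrize(
        "a,u,ai", [(10.0, 10.0, 0.0), (15.0, 10.0, 0.2), (0.0, 5.0, -1.0)]
    )
    def test_worked_values(self, a, u, ai):
        assert attention_index(a, u) == pytest.approx(ai)

    def test_undefined_when_both_zero(self):
        assert np.isnan(attention_index(0.0, 0.0))

    def test_identities_on_randomized_inputs(self):
        """AI in [-1,1]; modulation ratio equals A/U (1000 cases)."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a, u = rng.uniform(0.01, 50.0, 2)
            ai = attention_index(a, u)
            assert -1.0 <= ai <= 1.0
            assert modulation_ratio(ai) == pytest.approx(a / u, rel=1e-9)

    def test_classification_trivial_cases(self):
        same = np.full(50, 4.0)
        sig, sign, p = classify_modulation(same, same)
        assert not sig
        rng = np.random.default_rng(2)
        base = rng.normal(5, 0.5, 50)
        up = base + 5.0
        sig, sign, p = classify_modulation(up, base)
        assert sig and sign == 1
        sig, sign, p = classify_modulation(np.zeros(10), np.zeros(10))
        assert not sig

    def test_type_one_error_calibrated(self):
        """Null rejection rate ~ alpha over many simulated neurons."""
        rng = np.random.default_rng(123)
        n_tests, alpha = 4000, 0.05
        rej = 0
        for _ in range(n_tests):
            a = rng.normal(5, 1, 10)
            b = rng.normal(5, 1, 10)
            sig, _, _ = classify_modulation(a, b, alpha=alpha)
            rej += sig
        rate = rej / n_tests
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < 4 * se


class TestBootstrap:
    def test_identical_proportions_not_significant(self):
        res = bootstrap_proportion_test((1000, 600), (1000, 600), seed=0)
        assert res.p_value > 0.5

    def test_published_counts_are_significant(self):
        # 169/271 positively-modulated excitatory vs 51/67 inhibitory
        res = bootstrap_proportion_test((271, 169), (67, 51), seed=0)
        assert res.p_value < 0.05

    def test_deterministic_under_fixed_seed(self):
        a = bootstrap_proportion_test((100, 70), (50, 20), seed=5)
        b = bootstrap_proportion_test((100, 70), (50, 20), seed=5)
        assert a.p_value == b.p_value


class TestDiscriminability:
    @pytest.mark.parametrize(
        "args,expected",
        [((10.0, 2.0, 10.0, 2.0), 0.0), ((10.0, 2.0, 6.0, 2.0), 2.0)],
    )
    def test_worked_values(self, args, expected):
        assert discriminability(*args).d_prime == pytest.approx(expected)

    def test_antisymmetry_and_scale_invariance(self):
        """Swapping stimuli negates d'; common scaling leaves it unchanged
        (1000 randomized cases)."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            m1, m2 = rng.uniform(0, 30, 2)
            s1, s2 = rng.uniform(0.1, 5, 2)
            d = discriminability(m1, s1, m2, s2).d_prime
            assert discriminability(m2, s2, m1, s1).d_prime == pytest.approx(-d)
            c = rng.uniform(0.1, 10)
            assert discriminability(c * m1, c * s1, c * m2, c * s2).d_prime == (
                pytest.approx(d)
            )
            assert np.sign(d) == np.sign(m1 - m2) or m1 == m2

    def test_mean_denominator_variant(self):
        d = discriminability(10.0, 1.0, 6.0, 3.0, denominator="mean")
        assert d.d_prime == pytest.approx(4.0 / 2.0)

    def test_degenerate_zero_sd(self):
        assert np.isinf(discriminability(5.0, 0.0, 1.0, 0.0).d_prime)
        assert discriminability(5.0, 0.0, 5.0, 0.0).d_prime == 0.0
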