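"""Connectivity sampling and network realization."""

import numpy as np
import pytest
from scipy import stats

from laminet import build_inter_mc, build_intra_mc, build_network, sample_connections
from laminet.config import load_model_spec, scale_spec
from laminet.network import NetworkSizeError, estimate_edge_count
from laminet._sampling import sample_pathway_bruteforce


class TestSampleConnections:
    def test_zero_probability_gives_no_edges(self):
        pre, post = sample_connections(50, 50, 0.0, seed=1)
        assert pre.size == 0 and post.size == 0

    def test_full_probability_forces_all_pairs(self):
        pre, post = sample_connections(3, 2, 1.0, seed=1)
        assert sorted(zip(pre, post)) == [
            (0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)
        ]

    def test_edge_count_matches_binomial(self):
        # N_pre = N_post = 200 disjoint populations at the L2/3e->L2/3e prob
        c, n = 0.1960, 200
        counts = [
            sample_connections(n, n, c, seed=s)[0].size for s in range(10)
        ]
        mean, sd = n * n * c, np.sqrt(n * n * c * (1 - c))
        for cnt in counts:
            assert abs(cnt - mean) < 4 * sd

    def test_no_autapses_or_multapses(self):
        pre, post = sample_connections(40, 40, 0.5, seed=3, same_population=True)
        pairs = list(zip(pre.tolist(), post.tolist()))
        assert len(pairs) == len(set(pairs))
        assert all(p != q for p, q in pairs)

    def test_matches_bruteforce_bernoulli_distribution(self):
        """Fast sampler and literal pairwise coin-flip sampler agree in
        distribution (two-sample KS on in-degrees, tiny populations)."""
        c, n_pre, n_post = 0.3, 8, 8
        fast, brute = [], []
        for s in range(400):
            pre, post = sample_connections(n_pre, n_post, c, seed=s,
                                           same_population=True)
            fast.extend(np.bincount(post, minlength=n_post))
            rng = np.random.default_rng(s)
            bp, bq = sample_pathway_bruteforce(rng, n_pre, n_post, c, True)
            brute.extend(np.bincount(bq, minlength=n_post))
        res = stats.ks_2samp(fast, brute)
        assert res.pvalue > 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_connections(10, 10, 1.5, seed=0)
        with pytest.raises(ValueError):
            sample_connections(0, 10, 0.5, seed=0)


class TestIntraMc:
    def test_zero_pathways_have_no_edges(self, fixture_net):
        spec, net = fixture_net
        pre, post, w, d = build_intra_mc(spec, 0, seed=5)
        # L5i and L6i project nowhere above their own layer
        for src, dst in (("L5i", "L23e"), ("L5i", "L23i"),
                         ("L6i", "L23e"), ("L6i", "L4e"), ("L6i", "L5e")):
            s = net.pop_slice(0, src)
            t = net.pop_slice(0, dst)
            mask = (pre >= s.start) & (pre < s.stop) & (post >= t.start) & (post < t.stop)
            assert mask.sum() == 0

    def test_realized_indegree_near_expectation(self):
        spec = load_model_spec(
            {"populations": {l: {"e": 120, "i": 120} for l in ("L23", "L4", "L5", "L6")}}
        )
        pre, post, w, d = build_intra_mc(spec, 0, seed=11)
        # L4e -> L2/3e at C = 0.1405
        s = spec.population_size("L4e")
        l4e = slice(240, 360)  # population order: L23e, L23i, L4e, ...
        l23e = slice(0, 120)
        mask = (pre >= l4e.start) & (pre < l4e.stop) & (post < l23e.stop)
        mean_indeg = mask.sum() / 120
        expect = 0.1405 * 120
        sd = np.sqrt(120 * 0.1405 * (1 - 0.1405) / 120)
        assert abs(mean_indeg - expect) < 4 * sd

    def test_deterministic_from_seed(self, fixture_net):
        spec, _ = fixture_net
        a = build_intra_mc(spec, 2, seed=9)
        b = build_intra_mc(spec, 2, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_inhibitory_sources_have_negative_weights(self, fixture_net):
        spec, net = fixture_net
        pre, post, w, d = build_intra_mc(spec, 0, seed=5)
        inh = np.zeros(net.n_neurons, bool)
        for pop in ("L23i", "L4i", "L5i", "L6i"):
            s = net.pop_slice(0, pop)
            inh[s.start:s.stop] = True
        assert np.all(w[inh[pre]] < 0)
        assert np.all(w[~inh[pre]] > 0)


class TestInterMc:
    def test_ablation_removes_exc_exc(self, fixture_net):
        import copy
        import dataclasses

        spec, net = fixture_net
        spec_off = copy.deepcopy(spec)
        spec_off.inter_mc = dataclasses.replace(spec.inter_mc, enable_exc_exc=False)
        pre, post, w, d = build_inter_mc(spec_off, seed=13)
        # all edges must end on L2/3i populations (lateral inhibition only)
        on_i = np.zeros(net.n_neurons, bool)
        for mc in range(8):
            s = net.pop_slice(mc, "L23i")
            on_i[s.start:s.stop] = True
        assert on_i[post].all()

    def test_exc_exc_targets_exactly_two_neighbors(self, fixture_net):
        spec, net = fixture_net
        pre, post, w, d = build_inter_mc(spec, seed=13)
        mc_of = np.zeros(net.n_neurons, int)
        is_e = np.zeros(net.n_neurons, bool)
        for mc in range(8):
            for pop in ("L23e", "L23i"):
                s = net.pop_slice(mc, pop)
                mc_of[s.start:s.stop] = mc
                if pop == "L23e":
                    is_e[s.start:s.stop] = True
        ee = is_e[post]
        for a in range(8):
            targets = set(mc_of[post[ee][mc_of[pre[ee]] == a]])
            assert targets == {(a - 1) % 8, (a + 1) % 8}

    def test_lateral_inhibition_count_within_binomial_bounds(self, fixture_net):
        spec, net = fixture_net
        pre, post, w, d = build_inter_mc(spec, seed=13)
        is_i = np.zeros(net.n_neurons, bool)
        for mc in range(8):
            s = net.pop_slice(mc, "L23i")
            is_i[s.start:s.stop] = True
        n_ei = int(is_i[post].sum())
        n_e = n_i = 20
        trials = 56 * n_e * n_i
        mean = trials * 0.03
        sd = np.sqrt(trials * 0.03 * 0.97)
        assert abs(n_ei - mean) < 4 * sd


class TestBuildNetwork:
    def test_reference_scale_neuron_count_without_building(self, reference_spec):
        assert reference_spec.total_neurons == 154352

    def test_memory_guard_refuses_oversized_build(self, reference_spec):
        with pytest.raises(NetworkSizeError, match="scale_spec"):
            build_network(reference_spec, seed=0, max_edges=1000)

    def test_edge_estimate_scales_quadratically(self, reference_spec):
        full = estimate_edge_count(reference_spec)
        half = estimate_edge_count(scale_spec(reference_spec, 0.5))
        assert half == pytest.approx(full / 4, rel=0.02)

    def test_same_seed_identical_network_hash(self, fixture_net):
        spec, net = fixture_net
        net2 = build_network(spec, seed=7)
        assert net2.content_hash() == net.content_hash()
        net3 = build_network(spec, seed=8)
        assert net3.content_hash() != net.content_hash()

    def test_all_edges_reference_existing_neurons(self, fixture_net):
        spec, net = fixture_net
        assert net.pre.min() >= 0 and net.pre.max() < net.n_neurons
        assert net.post.min() >= 0 and net.post.max() < net.n_neurons
        assert np.all(net.delay > 0)

    def test_edge_list_text_round_trip(self, fixture_net, tmp_path):
        spec, net = fixture_net
        path = tmp_path / "edges.tsv"
        net.save_edges(path)
        loaded = type(net).load_edges(path)
        assert loaded.n_neurons == net.n_neurons
        assert np.array_equal(loaded.pre, net.pre)
        assert np.array_equal(loaded.post, net.post)
        np.testing.assert_allclose(loaded.weight, net.weight, rtol=1e-5)
        np.testing.assert_allclose(loaded.delay, net.delay, rtol=1e-4)
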