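"""Synchronization observables against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netsync import (
    CoherenceMatrix,
    average_wns,
    clrp,
    effective_coupling,
    global_order_parameter,
    local_order_parameter,
    mean_ppc_split,
    pairwise_phase_coherence,
    ppc_by_degree_product,
    skeleton,
)
from netsync.coherence import link_ranks

from conftest import make_record


def symmetric_matrix(rng: np.random.Generator, n: int) -> CoherenceMatrix:
    w = rng.uniform(0, 1, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return CoherenceMatrix(weights=w)


class TestGlobalOrder:
    def test_identical_phases_give_unity(self):
        rec = make_record(np.full((20, 8), 1.3))
        assert global_order_parameter(rec) == pytest.approx(1.0)

    def test_roots_of_unity_cancel(self):
        theta = 2 * np.pi * np.arange(4) / 4
        rec = make_record(np.tile(theta, (5, 1)))
        assert global_order_parameter(rec) == pytest.approx(0.0, abs=1e-12)

    def test_incoherent_baseline_closed_form(self):
        # E|mean of N unit phasors| = sqrt(pi) / (2 sqrt(N)) for iid uniform
        rng = np.random.default_rng(0)
        n = 512
        vals = [
            global_order_parameter(make_record(rng.uniform(-np.pi, np.pi, (1, n))))
            for _ in range(100)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert abs(np.mean(vals) - expected) < 3 * np.std(vals) / np.sqrt(100) + 0.005


class TestLocalOrder:
    def test_coherent_neighborhood(self):
        g = nx.star_graph(4)
        theta = np.zeros((10, 5))
        theta[:, 0] = 2.0  # center phase is irrelevant to its own r_i
        r = local_order_parameter(make_record(theta), g)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_degree_one_always_unity(self):
        g = nx.path_graph(3)
        rng = np.random.default_rng(1)
        r = local_order_parameter(make_record(rng.uniform(-np.pi, np.pi, (50, 3))), g)
        assert r[0] == pytest.approx(1.0)
        assert r[2] == pytest.approx(1.0)

    def test_star_center_random_walk_level(self):
        # center of a k=100 star with random leaf phases: E r ~ sqrt(pi)/(2*10)
        g = nx.star_graph(100)
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(200):
            theta = rng.uniform(-np.pi, np.pi, (1, 101))
            vals.append(local_order_parameter(make_record(theta), g)[0])
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi) / 20, rel=0.1)

    def test_isolated_node_rejected(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            local_order_parameter(make_record(np.zeros((2, 3))), g)


class TestPairwiseCoherence:
    def test_locked_pair_any_offset(self):
        t = np.arange(100) * 0.1
        theta = np.stack([0.3 * t, 0.3 * t + 1.1], axis=1)
        c = pairwise_phase_coherence(make_record(theta))
        assert c.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_drifting_pair_discrete_closed_form(self):
        # theta_i - theta_j = dw * t sampled at t_m = m*h: |geometric sum|
        dw, h, T = 0.7, 0.1, 400
        t = h * np.arange(T)
        theta = np.stack([dw * t, np.zeros(T)], axis=1)
        c = pairwise_phase_coherence(make_record(theta, dt_eff=h))
        expected = abs(np.exp(1j * dw * t).mean())
        assert c.weights[0, 1] == pytest.approx(expected, abs=1e-12)
        # and the continuum sinc envelope is approached
        sinc = abs(np.sin(dw * T * h / 2) / (dw * T * h / 2))
        assert c.weights[0, 1] == pytest.approx(sinc, abs=0.02)

    def test_matrix_invariants(self, short_run):
        _, _, _, rec = short_run
        c = pairwise_phase_coherence(rec)
        assert np.array_equal(c.weights, c.weights.T)
        np.testing.assert_allclose(np.diag(c.weights), 1.0)
        assert c.weights.min() >= 0.0 and c.weights.max() <= 1.0

    def test_global_phase_shift_invariance(self, short_run):
        _, _, _, rec = short_run
        a = pairwise_phase_coherence(rec)
        b = pairwise_phase_coherence(make_record(rec.unwrapped + 2.1))
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)


class TestAverageWns:
    def test_identity_and_mixture(self):
        rng = np.random.default_rng(3)
        m = symmetric_matrix(rng, 6)
        np.testing.assert_array_equal(average_wns([m, m]).weights, m.weights)
        zeros = CoherenceMatrix(weights=np.eye(6) * 1.0 + 0.0)
        ones = CoherenceMatrix(weights=np.ones((6, 6)))
        avg = average_wns([zeros, ones])
        iu = np.triu_indices(6, 1)
        np.testing.assert_allclose(avg.weights[iu], 0.5)

    def test_size_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            average_wns([symmetric_matrix(rng, 4), symmetric_matrix(rng, 5)])

    def test_averaging_reduces_offdiagonal_variance(self, ba_small):
        from netsync import SimulationConfig, draw_initial_configuration, integrate

        cfg = dict(coupling=0.01, t_transient=10.0, t_measure=30.0)
        mats = []
        for seed in range(6):
            init = draw_initial_configuration(64, 100 + seed)
            rec = integrate(
                ba_small,
                SimulationConfig(rng_seed=200 + seed, **cfg),
                init,
            )
            mats.append(pairwise_phase_coherence(rec))
        iu = np.triu_indices(64, 1)
        single = np.var([m.weights[iu] for m in mats], axis=0).mean()
        grouped = [average_wns(mats[i : i + 2]).weights[iu] for i in (0, 2, 4)]
        pooled = np.var(grouped, axis=0).mean()
        # spread across averaged WNSs must sit below the single-run spread
        assert pooled < single


class TestSkeleton:
    def test_two_nodes(self):
        c = CoherenceMatrix(weights=np.array([[1.0, 0.4], [0.4, 1.0]]))
        t = skeleton(c)
        assert t.edges == ((0, 1),)
        assert t.total_weight == pytest.approx(0.4)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        n = 5
        for _ in range(5):
            c = symmetric_matrix(rng, n)
            pairs = list(itertools.combinations(range(n), 2))
            best = -1.0
            for subset in itertools.combinations(pairs, n - 1):
                g = nx.Graph(subset)
                if g.number_of_nodes() == n and nx.is_tree(g):
                    best = max(best, sum(c.weights[u, v] for u, v in subset))
            assert skeleton(c).total_weight == pytest.approx(best, abs=1e-12)

    def test_equal_weights_total_forced(self):
        w = np.full((6, 6), 0.3)
        np.fill_diagonal(w, 1.0)
        t = skeleton(CoherenceMatrix(weights=w))
        assert t.total_weight == pytest.approx(5 * 0.3)

    def test_beats_random_spanning_trees(self):
        rng = np.random.default_rng(6)
        c = symmetric_matrix(rng, 12)
        best = skeleton(c).total_weight
        for seed in range(20):
            t = nx.random_spanning_tree(nx.complete_graph(12), seed=seed)
            w = sum(c.weights[u, v] for u, v in t.edges)
            assert best >= w - 1e-12


class TestCLRP:
    def test_self_comparison_is_unity(self):
        rng = np.random.default_rng(7)
        m = symmetric_matrix(rng, 8)
        assert clrp(m, m) == 1.0

    def test_adjacent_swap_hand_value(self):
        # L=10 links (n=5); swapping ranks r and r+1 costs 2*(1/10)/10
        n = 5
        base = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        base[iu] = np.linspace(1.0, 0.1, 10)
        base = base + base.T
        np.fill_diagonal(base, 1.0)
        swapped = base.copy()
        (i0, j0), (i1, j1) = (iu[0][3], iu[1][3]), (iu[0][4], iu[1][4])
        swapped[i0, j0], swapped[i1, j1] = base[i1, j1], base[i0, j0]
        swapped[j0, i0], swapped[j1, i1] = base[j1, i1], base[j0, i0]
        a = CoherenceMatrix(weights=base)
        b = CoherenceMatrix(weights=swapped)
        assert clrp(a, b) == pytest.approx(1 - 2 * (1 / 10) / 10)

    def test_independent_rankings_expectation(self):
        # E|rank difference| of two independent permutations = (L^2-1)/(3L)
        rng = np.random.default_rng(8)
        n = 30
        L = n * (n - 1) // 2
        vals = [
            clrp(symmetric_matrix(rng, n), symmetric_matrix(rng, n))
            for _ in range(100)
        ]
        expected = 1 - (L**2 - 1) / (3 * L) / L
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)

    def test_rank_ties_broken_by_link_index(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 1.0)
        ranks = link_ranks(CoherenceMatrix(weights=w))
        np.testing.assert_array_equal(ranks, np.arange(1, 7))

    def test_size_mismatch(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            clrp(symmetric_matrix(rng, 4), symmetric_matrix(rng, 6))


class TestEffectiveCoupling:
    def test_linear_in_coupling_and_degree(self, ba_small):
        r = np.ones(64)
        assert np.all(effective_coupling(0.0, ba_small, r) == 0.0)
        k_eff = effective_coupling(0.1, ba_small, r)
        degs = np.array([ba_small.degree(i) for i in range(64)])
        np.testing.assert_allclose(k_eff, 0.1 * degs)
        # hub vs leaf at equal r: ratio of effective couplings = degree ratio
        hub, leaf = degs.argmax(), degs.argmin()
        assert k_eff[hub] / k_eff[leaf] == pytest.approx(degs[hub] / degs[leaf])

    def test_rejects_out_of_range_r(self, ba_small):
        with pytest.raises(ValueError):
            effective_coupling(0.1, ba_small, np.full(64, 1.5))


class TestSplitAndBinning:
    def test_split_on_indicator_weights(self, ba_small):
        import networkx as nx

        a = nx.to_numpy_array(ba_small)
        w = a.copy()
        np.fill_diagonal(w, 1.0)
        c = CoherenceMatrix(weights=w)
        conn, disc = mean_ppc_split(c, ba_small)
        assert conn == pytest.approx(1.0)
        assert disc == pytest.approx(0.0)

    def test_degree_product_bins_cover_all_pairs(self, ba_small):
        rng = np.random.default_rng(10)
        c = symmetric_matrix(rng, 64)
        centers, means = ppc_by_degree_product(c, ba_small)
        assert len(centers) == len(means) > 1
        assert np.all(np.diff(centers) > 0)
        assert np.all((means >= 0) & (means <= 1))
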