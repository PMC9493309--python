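"""Efficiency/vulnerability, natural connectivity, cohesion, removal curves."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from micronet import (AbundanceTable, cohesion, fixture_graph,
                      global_efficiency, natural_connectivity,
                      random_removal_curve, targeted_removal, vulnerability)


def bfs_efficiency_oracle(net):
    """Brute-force all-pairs BFS inverse-distance mean (independent of the
    implementation's shortest-path machinery)."""
    nodes = list(net.nodes)
    n = len(nodes)
    adj = {v: set(net.neighbors(v)) for v in nodes}
    total = 0.0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        for v, dv in dist.items():
            if v != src:
                total += 1.0 / dv
    return total / (n * (n - 1))


class TestEfficiency:
    def test_complete_k3(self):
        assert global_efficiency(fixture_graph("complete_k3")) == pytest.approx(1.0)

    def test_path_p3(self):
        assert global_efficiency(fixture_graph("path_p3")) == pytest.approx(5 / 6)

    def test_two_isolated_nodes(self):
        g = nx.empty_graph(2)
        assert global_efficiency(g) == 0.0

    def test_matches_bfs_oracle(self, rng):
        for _ in range(25):
            g = nx.gnp_random_graph(int(rng.integers(2, 30)),
                                    float(rng.random()),
                                    seed=int(rng.integers(2**31)))
            assert global_efficiency(g) == pytest.approx(
                bfs_efficiency_oracle(g), abs=1e-12)


class TestVulnerability:
    @pytest.mark.parametrize("name,expected", [
        ("path_p3", 1.0),       # cutting the middle node disconnects the rest
        ("complete_k3", 0.0),   # symmetric: every removal leaves K2 (E = 1)
        ("star_s5", 1.0),       # hub removal isolates all leaves
    ])
    def test_fixture_values(self, name, expected):
        v, _ = vulnerability(fixture_graph(name))
        assert v == pytest.approx(expected)

    def test_cycle_analytic(self):
        # C5 is vertex-transitive: deleting any node leaves P4, so V has a
        # closed form computed from E(C5) and E(P4)
        c5 = nx.cycle_graph(5)
        e_c5 = global_efficiency(c5)
        e_p4 = global_efficiency(nx.path_graph(4))
        v, _ = vulnerability(c5)
        assert v == pytest.approx((e_c5 - e_p4) / e_c5)

    def test_zero_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency zero"):
            vulnerability(nx.empty_graph(4))

    def test_argmax_node_is_cut_vertex(self):
        v, node = vulnerability(fixture_graph("star_s5"))
        assert node == 0


class TestNaturalConnectivity:
    def test_edgeless_zero(self):
        assert natural_connectivity(nx.empty_graph(7)) == 0.0

    def test_complete_k3_closed_form(self):
        expected = math.log((math.e**2 + 2 * math.e**-1) / 3)
        assert natural_connectivity(fixture_graph("complete_k3")) == \
            pytest.approx(expected, abs=1e-12)

    def test_path_p3_closed_form(self):
        s = math.sqrt(2)
        expected = math.log((math.e**s + 1 + math.e**-s) / 3)
        assert natural_connectivity(fixture_graph("path_p3")) == \
            pytest.approx(expected, abs=1e-12)

    def test_logsumexp_matches_naive(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            lam = np.linalg.eigvalsh(nx.to_numpy_array(g))
            naive = math.log(np.mean(np.exp(lam)))
            assert natural_connectivity(g) == pytest.approx(naive, abs=1e-10)

    def test_strict_decrease_on_edge_deletion_sampled(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            before = natural_connectivity(g)
            u, v = next(iter(g.edges))
            h = g.copy()
            h.remove_edge(u, v)
            assert natural_connectivity(h) < before


class TestCohesion:
    def _null_table(self, n_taxa=40, n_samples=24, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.lognormal(3, 1, size=(n_taxa, 1)),
                             size=(n_taxa, n_samples))
        counts[0] += 1  # guard all-zero sample
        return AbundanceTable(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)]))

    def test_deterministic(self):
        t = self._null_table()
        a = cohesion(t, n_null=50, seed=9)
        b = cohesion(t, n_null=50, seed=9)
        assert a.positive.equals(b.positive)
        assert a.neg_pos_ratio == b.neg_pos_ratio

    def test_sign_conventions(self):
        t = self._null_table(seed=4)
        rep = cohesion(t, n_null=50, seed=1)
        assert (rep.positive >= 0).all()
        assert (rep.negative <= 0).all()
        assert rep.neg_pos_ratio >= 0

    def test_anticorrelated_pair_dominates(self):
        rng = np.random.default_rng(5)
        m = 24
        phase = np.sin(np.linspace(0, 4 * np.pi, m))
        a = np.round(3000 + 2000 * phase).astype(int)
        b = np.round(3000 - 2000 * phase).astype(int)
        noise = rng.poisson(30, size=(8, m))
        counts = pd.DataFrame(np.vstack([a, b, noise]),
                              index=[f"t{i}" for i in range(10)],
                              columns=[f"s{j}" for j in range(m)])
        rep = cohesion(AbundanceTable(counts), n_null=100, seed=2)
        assert rep.neg_pos_ratio > 1

    def test_small_null_warns(self):
        with pytest.warns(UserWarning, match="n_null"):
            cohesion(self._null_table(), n_null=5, seed=0)


class TestRandomRemoval:
    def test_fraction_zero_equals_intact(self):
        g = nx.complete_graph(20)
        curve = random_removal_curve(g, n_replicates=5, seed=1)
        assert curve.mean_nc[0] == pytest.approx(natural_connectivity(g))
        assert curve.mean_avgd[0] == pytest.approx(19.0)

    def test_complete_graph_slopes_negative(self):
        curve = random_removal_curve(nx.complete_graph(20), n_replicates=20,
                                     seed=3)
        assert curve.nc_slope < 0
        assert curve.avgd_slope < 0

    def test_seed_reproducibility(self):
        g = nx.gnp_random_graph(30, 0.2, seed=8)
        c1 = random_removal_curve(g, n_replicates=10, seed=5)
        c2 = random_removal_curve(g, n_replicates=10, seed=5)
        assert np.array_equal(c1.mean_nc, c2.mean_nc)
        assert np.array_equal(c1.mean_avgd, c2.mean_avgd)

    def test_small_graph_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            random_removal_curve(nx.complete_graph(5), seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            random_removal_curve(nx.complete_graph(15), fractions=[0.0, 1.0],
                                 seed=0)


class TestTargetedRemoval:
    def test_singleton_mdp_equals_tdp(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        rep = targeted_removal(g, [0])
        assert rep.mdp_nc == pytest.approx(rep.tdp_nc)
        assert rep.mdp_avgd == pytest.approx(rep.tdp_avgd)

    def test_isolate_removal_raises_avg_degree(self):
        g = fixture_graph("triangle_plus_isolate")
        rep = targeted_removal(g, [3])
        # AvgD goes 1.5 -> 2.0: a negative "decline" of one third
        assert rep.tdp_avgd == pytest.approx(100 * (1.5 - 2.0) / 1.5)

    def test_star_hub_removal_total_collapse(self):
        rep = targeted_removal(fixture_graph("star_s5"), [0])
        assert rep.tdp_avgd == pytest.approx(100.0)

    def test_must_leave_two_nodes(self):
        with pytest.raises(ValueError, match="leave >= 2"):
            targeted_removal(fixture_graph("complete_k3"), [0, 1])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            targeted_removal(fixture_graph("complete_k4"), [])
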