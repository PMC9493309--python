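"""Topological panel, deterministic module detection, Zi-Pi roles, keystones."""

import math

import networkx as nx
import numpy as np
import pytest

from micronet import (ModulePartition, average_degree, detect_modules,
                      fixture_graph, keystone_sets, topology_panel, zi_pi)


def newman_q(net, module_of):
    """Independent modularity oracle: Q = sum_m (e_mm - a_m^2)."""
    m = net.number_of_edges()
    if m == 0:
        return 0.0
    e_mm, a_m = {}, {}
    for u, v in net.edges:
        if module_of[u] == module_of[v]:
            e_mm[module_of[u]] = e_mm.get(module_of[u], 0) + 1
    for node in net.nodes:
        a_m[module_of[node]] = a_m.get(module_of[node], 0) + net.degree(node)
    mods = set(module_of.values())
    return sum(e_mm.get(c, 0) / m - (a_m.get(c, 0) / (2 * m)) ** 2 for c in mods)


class TestPanel:
    def test_complete_k4(self):
        p = topology_panel(fixture_graph("complete_k4"))
        assert (p.total_nodes, p.total_links) == (4, 6)
        assert p.avg_degree == pytest.approx(3.0)
        assert p.avg_clustering == pytest.approx(1.0)
        assert p.avg_path_distance == pytest.approx(1.0)
        assert p.density == pytest.approx(1.0)

    def test_path_p3_mean_distance(self):
        p = topology_panel(fixture_graph("path_p3"))
        assert p.avg_path_distance == pytest.approx(4 / 3)

    def test_avg_degree_identity_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(rng.integers(2, 25), rng.random(),
                                    seed=int(rng.integers(2**31)))
            if g.number_of_nodes() == 0:
                continue
            p = topology_panel(g)
            assert p.avg_degree * p.total_nodes == pytest.approx(
                2 * p.total_links)
            assert 0 <= p.avg_clustering <= 1

    def test_disconnected_pairs_excluded_from_gd(self):
        g = fixture_graph("two_cliques_k4")
        p = topology_panel(g)
        assert p.avg_path_distance == pytest.approx(1.0)  # within-clique only

    def test_single_node_flagged(self):
        g = nx.Graph()
        g.add_node("x")
        p = topology_panel(g)
        assert p.avg_path_distance == 0.0
        assert not p.gd_defined


class TestDetectModules:
    def test_two_cliques(self):
        part = detect_modules(fixture_graph("two_cliques_k4"))
        assert part.n_modules == 2
        assert part.Q == pytest.approx(0.5)
        assert part.Q == pytest.approx(newman_q(fixture_graph("two_cliques_k4"),
                                                part.module_of), abs=1e-12)

    def test_single_clique(self):
        part = detect_modules(fixture_graph("complete_k4"))
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self, rng):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        p1, p2 = detect_modules(g), detect_modules(g)
        assert p1.module_of == p2.module_of
        assert p1.Q == p2.Q

    def test_edgeless_singletons(self):
        g = nx.empty_graph(5)
        part = detect_modules(g)
        assert part.n_modules == 5
        assert part.Q == 0.0

    def test_q_matches_newman_oracle(self, rng):
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.2, seed=seed)
            if g.number_of_edges() == 0:
                continue
            part = detect_modules(g)
            assert part.Q == pytest.approx(newman_q(g, part.module_of),
                                           abs=1e-12)

    def test_major_module_count(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(2))
        part = detect_modules(g)
        assert part.n_modules == 2
        assert part.n_major_modules(min_size=5) == 1


class TestZiPi:
    def test_all_links_within_module(self):
        g = fixture_graph("complete_k4")
        part = ModulePartition({n: 0 for n in g.nodes}, 0.0)
        roles = zi_pi(g, part)
        assert (roles["pi"] == 0).all()
        assert (roles["zi"] == 0).all()  # equal within-degree, zero variance

    def test_even_split_participation(self):
        g = nx.Graph([("c", "a1"), ("c", "a2"), ("c", "b1"), ("c", "b2")])
        part = ModulePartition({"c": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}, 0.0)
        roles = zi_pi(g, part)
        assert roles.loc["c", "pi"] == pytest.approx(0.5)

    def test_zi_standardisation(self, rng):
        g = nx.gnp_random_graph(60, 0.12, seed=3)
        part = detect_modules(g)
        roles = zi_pi(g, part)
        for m, sub in roles.groupby("module"):
            kappa_distinct = sub["zi"].nunique()
            if len(sub) > 1 and kappa_distinct > 1:
                assert sub["zi"].mean() == pytest.approx(0.0, abs=1e-9)
                assert sub["zi"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_degree_zero_peripheral(self):
        g = fixture_graph("triangle_plus_isolate")
        part = detect_modules(g)
        roles = zi_pi(g, part)
        assert roles.loc[3, "role"] == "peripheral"
        assert roles.loc[3, "pi"] == 0.0

    def test_pi_upper_bound(self, rng):
        g = nx.gnp_random_graph(40, 0.2, seed=9)
        part = detect_modules(g)
        roles = zi_pi(g, part)
        assert ((roles["pi"] >= 0) & (roles["pi"] < 1)).all()


class TestKeystones:
    def test_star_top_degree(self):
        g = fixture_graph("star_s5")
        part = detect_modules(g)
        _, top = keystone_sets(g, zi_pi(g, part))
        assert top == {0}  # ceil(0.1*5) = 1 node: the hub

    def test_tie_broken_by_node_id(self):
        g = nx.Graph([("a", "b"), ("c", "d")])  # all degree 1
        part = detect_modules(g)
        _, top = keystone_sets(g, zi_pi(g, part))
        assert top == {"a"}

    def test_all_peripheral_no_hubs(self):
        g = fixture_graph("complete_k4")
        part = detect_modules(g)
        hubs, _ = keystone_sets(g, zi_pi(g, part))
        assert hubs == set()

    def test_top_set_size(self, rng):
        g = nx.gnp_random_graph(37, 0.2, seed=2)
        part = detect_modules(g)
        roles = zi_pi(g, part)
        hubs, top = keystone_sets(g, roles, top_fraction=0.10)
        assert len(top) == math.ceil(0.10 * 37)
        assert top <= set(g.nodes) and hubs <= set(g.nodes)


def test_average_degree_helper():
    assert average_degree(279, 1329) == pytest.approx(2 * 1329 / 279)
    with pytest.raises(ValueError):
        average_degree(0, 5)
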