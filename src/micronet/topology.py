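"""Topological panel, module detection, and Zi-Pi keystone classification.

All topology metrics are computed on the unsigned, unweighted skeleton of the
signed network; edge signs are consumed only by cohesion and edge reporting.
Module detection is the deterministic greedy (CNM) modularity maximisation,
so repeated runs give identical partitions, modularity values and node roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ZI_THRESHOLD = 2.5   # within-module degree z-score cutoff (Guimera-Amaral scheme)
PI_THRESHOLD = 0.62  # participation coefficient cutoff


def average_degree(n_nodes: int, n_links: int) -> float:
    """Average degree 2L/n of a network with n nodes and L links."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return 2.0 * n_links / n_nodes


@dataclass
class ModulePartition:
    module_of: dict
    Q: float

    def modules(self) -> dict:
        out: dict = {}
        for node, m in self.module_of.items():
            out.setdefault(m, set()).add(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def n_major_modules(self, min_size: int = 5) -> int:
        """Modules with >= ``min_size`` members (the usual convention for
        module-based role analysis, which disregards tiny fragments)."""
        return sum(1 for c in self.modules().values() if len(c) >= min_size)


@dataclass
class TopologyPanel:
    total_nodes: int
    total_links: int
    avg_degree: float
    avg_clustering: float
    avg_path_distance: float
    density: float
    modularity: float
    gd_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "total_nodes": self.total_nodes,
            "total_links": self.total_links,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "avg_path_distance": self.avg_path_distance,
            "density": self.density,
            "modularity": self.modularity,
        }


def detect_modules(net: nx.Graph) -> ModulePartition:
    """Deterministic greedy modularity communities on the unsigned skeleton.

    Isolated nodes form singleton modules. Module ids are assigned by the
    smallest member node, ascending, so output is stable across runs.
    """
    if net.number_of_nodes() == 0:
        return ModulePartition({}, 0.0)
    isolates = sorted(nx.isolates(net))
    core = net.subgraph([n for n in net.nodes if n not in set(isolates)])
    communities: list[set] = []
    if core.number_of_edges() > 0:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(core)]
    communities.extend({n} for n in isolates)
    communities.sort(key=lambda c: min(c))
    module_of = {n: m for m, c in enumerate(communities) for n in c}
    if net.number_of_edges() == 0:
        return ModulePartition(module_of, 0.0)
    q = float(nx.community.modularity(net, [set(c) for c in communities]))
    return ModulePartition(module_of, q)


def topology_panel(net: nx.Graph, partition: ModulePartition | None = None) -> TopologyPanel:
    """Standard co-occurrence panel: n, L, AvgD, AvgCC, GD, D, Q.

    GD averages shortest-path lengths over *connected* node pairs only
    (unit edge lengths); a single-node network reports GD = 0 with
    ``gd_defined=False``.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if partition is None:
        partition = detect_modules(net)
    L = net.number_of_edges()
    avg_cc = float(nx.average_clustering(net)) if n else 0.0
    total, pairs = 0.0, 0
    for node, dists in nx.all_pairs_shortest_path_length(net):
        for other, d in dists.items():
            if other != node:
                total += d
                pairs += 1
    gd_defined = pairs > 0
    gd = total / pairs if pairs else 0.0
    density = 2.0 * L / (n * (n - 1)) if n > 1 else 0.0
    return TopologyPanel(n, L, average_degree(n, L), avg_cc, gd, density,
                         partition.Q, gd_defined)


def zi_pi(net: nx.Graph, partition: ModulePartition,
          zi_threshold: float = ZI_THRESHOLD,
          pi_threshold: float = PI_THRESHOLD) -> pd.DataFrame:
    """Per-node within-module degree z-score (Zi), participation (Pi), role.

    Zi standardises the within-module degree kappa_i against its module's
    sample mean and sample (ddof=1) sd; Zi = 0 when the module has no degree
    variance. Pi = 1 - sum_s (kappa_is / k_i)^2 over modules s; Pi = 0 for
    degree-0 nodes. Roles follow the (zi_threshold, pi_threshold) quadrants:
    network_hub, module_hub, connector, peripheral.
    """
    missing = [n for n in net.nodes if n not in partition.module_of]
    if missing:
        raise ValueError(f"partition does not cover node {missing[0]!r}")
    nodes = sorted(net.nodes)
    mod = partition.module_of
    kappa = {}
    per_module_counts = {}
    for node in nodes:
        counts: dict = {}
        for nb in net.neighbors(node):
            counts[mod[nb]] = counts.get(mod[nb], 0) + 1
        per_module_counts[node] = counts
        kappa[node] = counts.get(mod[node], 0)
    # module-wise moments of kappa
    by_module: dict = {}
    for node in nodes:
        by_module.setdefault(mod[node], []).append(kappa[node])
    stats = {}
    for m, ks in by_module.items():
        arr = np.asarray(ks, dtype=float)
        sd = arr.std(ddof=1) if arr.size > 1 else 0.0
        stats[m] = (arr.mean(), sd)
    rows = []
    for node in nodes:
        k = net.degree(node)
        mean_k, sd_k = stats[mod[node]]
        zi = (kappa[node] - mean_k) / sd_k if sd_k > 0 else 0.0
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_counts[node].values())
        if zi > zi_threshold and pi > pi_threshold:
            role = "network_hub"
        elif zi > zi_threshold:
            role = "module_hub"
        elif pi > pi_threshold:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": node, "module": mod[node], "degree": k,
                     "zi": zi, "pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")


def keystone_sets(net: nx.Graph, roles: pd.DataFrame,
                  top_fraction: float = 0.10) -> tuple[set, set]:
    """Hub-role nodes and the ceil(top_fraction * n) highest-degree nodes.

    Degree ties at the cutoff are broken by node id ascending, so the set is
    deterministic.
    """
    hubs = set(roles.index[roles["role"] != "peripheral"])
    n = net.number_of_nodes()
    k = int(np.ceil(top_fraction * n))
    ranked = sorted(net.nodes, key=lambda v: (-net.degree(v), v))
    return hubs, set(ranked[:k])
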