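"""Network stability metrics and node-removal robustness simulations.

Implements the stability panel used in co-occurrence studies:

* global efficiency E = (1/(n(n-1))) * sum_{i != j} 1/d(i,j) with 1/inf = 0
  for disconnected pairs, and network vulnerability max_i (E - E_i)/E where
  E_i is the efficiency of the graph with node i deleted (normalised by its
  own, reduced node count);
* natural connectivity lambda_bar = ln((1/N) sum_i e^{lambda_i}) over the
  eigenvalues of the unsigned 0/1 adjacency matrix — a spectral robustness
  measure that strictly decreases whenever an edge is lost;
* abundance-weighted community cohesion (positive and negative components,
  null-corrected by taxon shuffles) and the Neg:Pos cohesion ratio;
* robustness under random node removal (regression slopes of natural
  connectivity and average degree against the removed fraction) and under
  targeted keystone removal (MDP: mean decline over single-node removals;
  TDP: decline after removing the whole set), both in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .abundance import AbundanceTable
from .topology import average_degree


def global_efficiency(net: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency requires >= 2 nodes")
    total = 0.0
    for node, dists in nx.all_pairs_shortest_path_length(net):
        for other, d in dists.items():
            if other != node:
                total += 1.0 / d
    return total / (n * (n - 1))


def vulnerability(net: nx.Graph) -> tuple[float, object]:
    """Maximal relative efficiency drop over single-node deletions.

    Returns (V, argmax node); ties broken by node id ascending. The deleted
    graph's efficiency uses its own (n-1) node count.
    """
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError("vulnerability requires >= 3 nodes")
    e = global_efficiency(net)
    if e == 0:
        raise ValueError("efficiency zero, vulnerability undefined")
    best_v, best_node = -np.inf, None
    for node in sorted(net.nodes):
        sub = net.subgraph([v for v in net.nodes if v != node])
        v = (e - global_efficiency(sub)) / e
        if v > best_v:
            best_v, best_node = v, node
    return float(best_v), best_node


def natural_connectivity(net: nx.Graph) -> float:
    """ln of the average of e^lambda over unsigned adjacency eigenvalues."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity requires >= 1 node")
    if net.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(net, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(logsumexp(lam) - np.log(n))


@dataclass
class CohesionReport:
    """Per-sample cohesion components and the Neg:Pos ratio."""

    positive: pd.Series           # per-sample positive cohesion, >= 0
    negative: pd.Series           # per-sample negative cohesion, <= 0
    neg_pos_ratio: float          # mean over usable samples of |neg|/pos
    neg_pos_ratio_of_means: float
    connectedness_pos: pd.Series  # per-taxon, >= 0
    connectedness_neg: pd.Series  # per-taxon, <= 0
    null_envelope: pd.DataFrame   # per-sample 95% envelope of |null cohesion|
    excluded_samples: list = field(default_factory=list)


def cohesion(table: AbundanceTable, n_null: int = 200, seed: int | None = None,
             ) -> CohesionReport:
    """Abundance-weighted, null-corrected cohesion per sample.

    Pairwise Pearson correlations of relative abundances are corrected by
    subtracting their expectation under ``n_null`` taxon-wise shuffles (each
    taxon's abundances permuted independently across samples). Per taxon,
    connectedness+ / connectedness- average the positive / negative corrected
    correlations; per sample, cohesion± = sum_i relabund_ij * connectedness_i±.
    The Neg:Pos ratio averages |negative|/positive over samples with positive
    cohesion > 0 (samples failing that are excluded and flagged).
    """
    import warnings

    if table.n_samples < 3:
        raise ValueError("cohesion requires >= 3 samples")
    if n_null < 10:
        warnings.warn("n_null < 10 gives an unreliable null correction", stacklevel=2)
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(dtype=float)
    depth = counts.sum(axis=0)
    if (depth == 0).any():
        raise ValueError("sample with zero total count")
    rel = counts / depth
    n_taxa, m = rel.shape

    def standardize(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # zero-variance taxa correlate 0 with everything
        return (x - mu) / sd

    z = standardize(rel)
    c_obs = z @ z.T / m
    np.fill_diagonal(c_obs, 0.0)

    null_sum = np.zeros_like(c_obs)
    null_mats = []
    for _ in range(n_null):
        shuffled = rng.permuted(rel, axis=1)
        # re-close the shuffled community so the null carries the same
        # compositional (unit-sum) constraint as the observed data
        colsum = shuffled.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        shuffled = shuffled / colsum
        zb = standardize(shuffled)
        # corr(observed taxon i, shuffled taxon k); kept asymmetric so the
        # null rows have the same sampling variance as the observed rows
        cb = z @ zb.T / m
        np.fill_diagonal(cb, 0.0)
        null_mats.append(cb)
        null_sum += cb
    null_mean = null_sum / n_null

    def split_connectedness(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = np.where(c > 0, c, 0.0)
        neg = np.where(c < 0, c, 0.0)
        npos = (c > 0).sum(axis=1)
        nneg = (c < 0).sum(axis=1)
        conn_p = np.divide(pos.sum(axis=1), npos, out=np.zeros(c.shape[0]),
                           where=npos > 0)
        conn_n = np.divide(neg.sum(axis=1), nneg, out=np.zeros(c.shape[0]),
                           where=nneg > 0)
        return conn_p, conn_n

    conn_p, conn_n = split_connectedness(c_obs - null_mean)
    coh_p = rel.T @ conn_p  # per sample
    coh_n = rel.T @ conn_n

    # null envelope: cohesion recomputed with each null draw's connectedness
    null_p = np.empty((n_null, m))
    null_n = np.empty((n_null, m))
    for b, cb in enumerate(null_mats):
        cp, cn = split_connectedness(cb - null_mean)
        null_p[b] = rel.T @ cp
        null_n[b] = rel.T @ cn
    env = pd.DataFrame(
        {
            "pos_hi": np.percentile(null_p, 97.5, axis=0),
            "neg_lo": np.percentile(null_n, 2.5, axis=0),
        },
        index=table.sample_ids,
    )

    samples = table.sample_ids
    pos = pd.Series(coh_p, index=samples, name="positive_cohesion")
    neg = pd.Series(coh_n, index=samples, name="negative_cohesion")
    usable = pos > 0
    excluded = list(pos.index[~usable])
    if not usable.any():
        raise ValueError("positive cohesion zero in every sample; ratio undefined")
    ratios = (neg[usable].abs() / pos[usable])
    ratio_of_means = float(neg[usable].abs().mean() / pos[usable].mean())
    return CohesionReport(
        pos, neg, float(ratios.mean()), ratio_of_means,
        pd.Series(conn_p, index=table.taxon_ids, name="connectedness_pos"),
        pd.Series(conn_n, index=table.taxon_ids, name="connectedness_neg"),
        env, excluded,
    )


@dataclass
class RobustnessCurve:
    fractions: np.ndarray
    mean_nc: np.ndarray
    mean_avgd: np.ndarray
    nc_slope: float
    avgd_slope: float
    n_replicates: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions, "mean_nc": self.mean_nc,
                             "mean_avgd": self.mean_avgd})


def random_removal_curve(net: nx.Graph, fractions=None, n_replicates: int = 100,
                         seed: int | None = None) -> RobustnessCurve:
    """Natural connectivity and average degree under random node loss.

    For each replicate and fraction f, round(f*n) nodes are removed
    (uniform, without replacement, fresh draw per fraction); metrics are
    averaged over replicates and regressed (OLS) against f.
    """
    n = net.number_of_nodes()
    if n < 10:
        raise ValueError("random removal requires >= 10 nodes")
    if fractions is None:
        fractions = np.round(np.arange(0.0, 0.501, 0.05), 10)
    fractions = np.asarray(fractions, dtype=float)
    if (fractions >= 1).any() or (fractions < 0).any():
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    nc = np.zeros((n_replicates, fractions.size))
    avgd = np.zeros((n_replicates, fractions.size))
    for rep in range(n_replicates):
        for fi, f in enumerate(fractions):
            k = int(round(f * n))
            if k == 0:
                sub = net
            else:
                drop = set(rng.choice(len(nodes), size=k, replace=False))
                sub = net.subgraph([v for i, v in enumerate(nodes) if i not in drop])
            m = sub.number_of_nodes()
            nc[rep, fi] = natural_connectivity(sub) if m else 0.0
            avgd[rep, fi] = average_degree(m, sub.number_of_edges()) if m else 0.0
    mean_nc = nc.mean(axis=0)
    mean_avgd = avgd.mean(axis=0)
    nc_slope = float(np.polyfit(fractions, mean_nc, 1)[0])
    avgd_slope = float(np.polyfit(fractions, mean_avgd, 1)[0])
    return RobustnessCurve(fractions, mean_nc, mean_avgd, nc_slope, avgd_slope,
                           n_replicates, seed)


@dataclass
class TargetedRemovalReport:
    keystone_set: str
    mdp_nc: float
    mdp_avgd: float
    tdp_nc: float
    tdp_avgd: float

    def to_dict(self) -> dict:
        return {"keystone_set": self.keystone_set, "mdp_nc": self.mdp_nc,
                "mdp_avgd": self.mdp_avgd, "tdp_nc": self.tdp_nc,
                "tdp_avgd": self.tdp_avgd}


def targeted_removal(net: nx.Graph, keystone_set, label: str = "keystone",
                     ) -> TargetedRemovalReport:
    """Percent decline of NC and AvgD under keystone removal.

    MDP: mean over single-node removals from the intact network; TDP:
    simultaneous removal of the whole set. Declines can be negative (a
    metric may rise when a low-degree node is removed).
    """
    keystone = sorted(keystone_set)
    if not keystone:
        raise ValueError("keystone set is empty")
    missing = [v for v in keystone if v not in net]
    if missing:
        raise ValueError(f"keystone node {missing[0]!r} not in network")
    n = net.number_of_nodes()
    if n - len(keystone) < 2:
        raise ValueError("removal must leave >= 2 nodes")
    nc0 = natural_connectivity(net)
    avgd0 = average_degree(n, net.number_of_edges())
    if nc0 == 0 or avgd0 == 0:
        raise ValueError("intact metric is zero; declined proportion undefined")

    def decline(metric0: float, metric1: float) -> float:
        return 100.0 * (metric0 - metric1) / metric0

    mdp_nc, mdp_avgd = [], []
    for node in keystone:
        sub = net.subgraph([v for v in net.nodes if v != node])
        mdp_nc.append(decline(nc0, natural_connectivity(sub)))
        mdp_avgd.append(decline(avgd0, average_degree(n - 1, sub.number_of_edges())))
    drop = set(keystone)
    sub = net.subgraph([v for v in net.nodes if v not in drop])
    tdp_nc = decline(nc0, natural_connectivity(sub))
    tdp_avgd = decline(avgd0, average_degree(sub.number_of_nodes(),
                                             sub.number_of_edges()))
    return TargetedRemovalReport(label, float(np.mean(mdp_nc)),
                                 float(np.mean(mdp_avgd)), tdp_nc, tdp_avgd)
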