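"""Synthetic grouped ASV tables with known correlation structure.

The generator emulates the kind of data the downstream network pipeline is
built for: a soil-style community of a few hundred taxa surveyed in a handful
of samples per habitat group, with a block (module) correlation structure on
log-abundances, a tunable fraction of negative associations inside modules,
and sequencing realised as fixed-depth multinomial counts with gamma
(negative-binomial marginal) overdispersion.

Latent model, per sample j: each module m draws a factor f_mj ~ N(0,1); a
module member i has log-abundance mu_i + l_i * f_mj + sigma * eps_ij, where a
``neg_edge_fraction`` of members carry a negative loading l_i (creating
negative within-module correlations). sigma is solved numerically so the
expected within-module |Pearson r| of the log-abundances equals
``within_module_corr``. Background taxa get independent log-normal
abundances, providing a clean correlation null.

Ground truth: all within-module pairs are true edges with sign
sign(l_i * l_k); the designed hub of each module is its largest-|loading|
member.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .abundance import AbundanceTable


@dataclass
class CommunitySpec:
    """Parameters of the synthetic community.

    Defaults mirror a small grouped soil survey: 3 habitat groups of 6
    samples, 300 taxa of which 3 modules of 40 carry signal, sequencing depth
    10,000 reads/sample.
    """

    n_samples_per_group: int = 6
    n_groups: int = 3
    n_taxa: int = 300
    n_modules: int = 3
    module_sizes: list[int] = None
    within_module_corr: float = 0.75
    neg_edge_fraction: float = 0.30
    sequencing_depth: int = 10_000
    nb_dispersion: float = 5.0
    baseline_logmean_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [40] * self.n_modules
        for name in ("n_samples_per_group", "n_groups", "n_taxa", "n_modules",
                     "sequencing_depth", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_samples_per_group < 1 or self.n_groups < 1 or self.n_taxa < 1:
            raise ValueError("sample/group/taxa counts must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any((not isinstance(s, (int, np.integer))) or s < 0 for s in self.module_sizes):
            raise ValueError("module_sizes must be non-negative integers")
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError("sum(module_sizes) exceeds n_taxa")
        if self.n_modules and not (0 < self.within_module_corr < 1):
            raise ValueError("within_module_corr must be in (0, 1)")
        if not (0 <= self.neg_edge_fraction <= 1):
            raise ValueError("neg_edge_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.baseline_logmean_sd < 0:
            raise ValueError("baseline_logmean_sd must be >= 0")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")


@dataclass
class GroundTruth:
    """Module labels (-1 = background), signed true edge set, designed hubs.

    ``log_abundance`` carries the latent (pre-sequencing) log-abundance
    matrix, on which ``within_module_corr`` is calibrated exactly; it lets
    downstream recovery tests separate correlation-structure questions from
    count-realisation noise.
    """

    module_label: pd.Series
    true_edges: dict  # (taxon_a, taxon_b) sorted tuple -> +1/-1
    designed_hubs: set = field(default_factory=set)
    log_abundance: pd.DataFrame = None

    def to_json(self, path) -> None:
        payload = {
            "module_label": {str(k): int(v) for k, v in self.module_label.items()},
            "true_edges": [[a, b, int(s)] for (a, b), s in sorted(self.true_edges.items())],
            "designed_hubs": sorted(self.designed_hubs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _solve_noise_sd(loadings_abs: np.ndarray, target: float) -> float:
    """Noise sd such that the mean pairwise |r| of module members hits target.

    For taxa with loadings l_i and iid noise sd s, |r_ik| =
    g_i*g_k with g_i = |l_i|/sqrt(l_i^2 + s^2); solve mean_{i<k} g_i g_k = target.
    """

    def mean_abs_r(s2: float) -> float:
        g = loadings_abs / np.sqrt(loadings_abs**2 + s2)
        tot = g.sum()
        # mean over unordered pairs of g_i * g_k
        num = (tot**2 - (g**2).sum()) / 2.0
        npairs = len(g) * (len(g) - 1) / 2.0
        return num / npairs

    lo, hi = 1e-12, 1e6
    if mean_abs_r(lo) <= target:
        return float(np.sqrt(lo))
    return float(np.sqrt(brentq(lambda s2: mean_abs_r(s2) - target, lo, hi)))


def generate_counts(spec: CommunitySpec) -> tuple[AbundanceTable, GroundTruth]:
    """Draw one grouped count table plus its ground truth. Seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_samples_per_group * spec.n_groups
    n_mod_taxa = sum(spec.module_sizes)

    taxa = [f"ASV{i:04d}" for i in range(spec.n_taxa)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    groups = pd.Series(
        [f"G{j // spec.n_samples_per_group + 1}" for j in range(n_samples)],
        index=samples, name="group",
    )

    labels = np.full(spec.n_taxa, -1, dtype=int)
    start = 0
    for m, size in enumerate(spec.module_sizes):
        labels[start:start + size] = m
        start += size

    mu = rng.normal(0.0, spec.baseline_logmean_sd, size=spec.n_taxa)
    loadings = np.zeros(spec.n_taxa)
    if n_mod_taxa:
        # wide loading spread, with one designated hub per module carrying a
        # clearly larger loading and the module's largest baseline abundance:
        # the designed hub is meant to be a detectable keystone target, not a
        # marginal one swamped by count noise
        mags = rng.uniform(0.5, 1.1, size=n_mod_taxa)
        start = 0
        for size in spec.module_sizes:
            if size:
                hub_at = start + int(rng.integers(size))
                mags[hub_at] = 1.5
                members = slice(start, start + size)
                mu[hub_at] = mu[members].max()
            start += size
        signs = np.where(rng.random(n_mod_taxa) < spec.neg_edge_fraction, -1.0, 1.0)
        loadings[:n_mod_taxa] = mags * signs
        sigma = _solve_noise_sd(np.abs(loadings[:n_mod_taxa]), spec.within_module_corr)
    else:
        sigma = 1.0

    logab = np.tile(mu[:, None], (1, n_samples))
    eps = rng.normal(size=(spec.n_taxa, n_samples))
    if spec.n_modules:
        factors = rng.normal(size=(spec.n_modules, n_samples))
        for i in range(n_mod_taxa):
            logab[i] += loadings[i] * factors[labels[i]]
        logab[:n_mod_taxa] += sigma * eps[:n_mod_taxa]
    # background taxa: independent log-normal with unit log-sd
    logab[n_mod_taxa:] += eps[n_mod_taxa:]

    counts = np.zeros((spec.n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        x = logab[:, j] - logab[:, j].max()
        p = np.exp(x)
        # gamma-multinomial mixture: NB-marginal overdispersion at fixed depth
        w = p * rng.gamma(spec.nb_dispersion, 1.0 / spec.nb_dispersion, size=spec.n_taxa)
        w /= w.sum()
        counts[:, j] = rng.multinomial(spec.sequencing_depth, w)

    table = AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples), groups)

    true_edges: dict = {}
    start = 0
    hubs: set = set()
    for m, size in enumerate(spec.module_sizes):
        members = range(start, start + size)
        for i, k in itertools.combinations(members, 2):
            sign = 1 if loadings[i] * loadings[k] > 0 else -1
            true_edges[(taxa[i], taxa[k])] = sign
        if size:
            hub = start + int(np.argmax(np.abs(loadings[start:start + size])))
            hubs.add(taxa[hub])
        start += size

    truth = GroundTruth(
        pd.Series(labels, index=taxa, name="module"), true_edges, hubs,
        pd.DataFrame(logab, index=taxa, columns=samples),
    )
    return table, truth


_FIXTURES = {
    "complete_k3": lambda: nx.complete_graph(3),
    "complete_k4": lambda: nx.complete_graph(4),
    "path_p3": lambda: nx.path_graph(3),
    "star_s5": lambda: nx.star_graph(4),
    "two_cliques_k4": lambda: nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
    "triangle_plus_isolate": lambda: _triangle_plus_isolate(),
}


def _triangle_plus_isolate() -> nx.Graph:
    g = nx.complete_graph(3)
    g.add_node(3)
    return g


def fixture_graph(name: str) -> nx.Graph:
    """A named small graph with all edge signs positive and weight 1."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FIXTURES))}"
        )
    g = _FIXTURES[name]()
    nx.set_edge_attributes(g, 1, "sign")
    nx.set_edge_attributes(g, 1.0, "weight")
    return g
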