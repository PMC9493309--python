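# micronet

Co-occurrence network construction and stability analysis for microbial
(amplicon/ASV) count tables.

Soil and other environmental microbiome studies routinely summarise a
community not only by who is there, but by how taxa co-vary: a co-occurrence
network whose nodes are ASVs and whose edges are strong pairwise abundance
correlations, signed by correlation direction. `micronet` implements that
workflow end to end for grouped sample designs (e.g. habitats sampled at
several time points), together with the stability panel used to compare such
networks:

1. **Filtering** — retain ASVs observed (count ≥ 4) in at least 20% of
   samples, then log-relative transform.
2. **Objective thresholding by random-matrix theory (RMT)** — instead of an
   arbitrary correlation cutoff, scan cutoffs *t* and test the
   nearest-neighbour spacing distribution (NNSD) of the truncated similarity
   matrix's unfolded eigenvalues. Noise-dominated matrices follow
   Gaussian-orthogonal-ensemble statistics (Wigner surmise,
   P(s) = (πs/2)·e^(−πs²/4)); once the cutoff excludes the noise
   correlations the matrix decomposes into independent blocks and spacings
   become Poisson (P(s) = e^(−s)). The chosen threshold is the smallest *t*
   whose NNSD is consistent with Poisson statistics (χ² test, p ≥ α).
3. **Topology panel** — nodes n, links L, average degree (2L/n), average
   clustering coefficient, mean shortest-path distance over connected pairs,
   density, and modularity Q from deterministic greedy (CNM) module
   detection.
4. **Keystones** — within-module degree z-score Z_i and participation
   coefficient P_i = 1 − Σ_s (κ_is/k_i)² classify nodes as peripherals,
   module hubs, connectors or network hubs (cutoffs 2.5 / 0.62); keystone
   sets are the hub-role nodes and the top 10% of nodes by degree.
5. **Stability** —
   * global efficiency E = (1/(n(n−1))) Σ_{i≠j} 1/d(i,j) and network
     vulnerability V = max_i (E − E_i)/E;
   * natural connectivity λ̄ = ln((1/N) Σ e^{λ_i}) over adjacency
     eigenvalues, which strictly decreases with every lost edge;
   * abundance-weighted community cohesion (positive and negative
     components, corrected by a taxon-shuffle permutation null) and the
     Neg:Pos cohesion ratio;
   * robustness simulations: regression slopes of natural connectivity and
     average degree under random node removal, and mean/total declined
     proportions (MDP/TDP) under targeted keystone removal.

A synthetic community generator (latent factor blocks on log-abundances,
negative-binomial counts at fixed sequencing depth, known module labels,
true edge set and designed hub taxa) makes every stage testable without any
sequencing data.

## Worked example

```sh
# simulate: 3 groups x 10 samples, 120 taxa, 3 modules of 20
cat > spec.yaml <<EOF
n_samples_per_group: 10
n_groups: 3
n_taxa: 120
n_modules: 3
module_sizes: [20, 20, 20]
within_module_corr: 0.8
EOF
micronet simulate --spec spec.yaml --seed 42 --out demo
micronet run --table demo/counts.tsv --groups demo/groups.tsv --out demo_run --seed 42
```

prints one line per group:

```
[G1] threshold=0.74 nodes=100 links=271 Q=0.558
[G2] threshold=0.72 nodes=114 links=287 Q=0.617
[G3] threshold=0.75 nodes=102 links=230 Q=0.614
```

Each group's RMT scan settled on a cutoff of 0.72–0.75 (at 10 samples per
group, null correlations are broad, so the transition to Poisson statistics
sits high), keeping ~100 of 120 taxa as non-isolated nodes. `demo_run/`
then holds per-group artifacts (edge list, RMT scan trace, node roles,
module map, removal curves) and `comparison.tsv`, a long-format metric ×
group table, e.g.:

| metric | G1 | G2 | G3 |
|---|---|---|---|
| avg_degree | 5.42 | 5.04 | 4.51 |
| modularity | 0.558 | 0.617 | 0.614 |
| natural_connectivity | 4.88 | 7.04 | 5.66 |
| vulnerability | 0.099 | 0.147 | 0.073 |
| neg_pos_cohesion | 0.648 | 0.746 | 0.741 |
| nc_slope_random | −5.75 | −8.98 | −7.64 |

Here G2's network is the most connective (highest natural connectivity) and
also degrades fastest under random node loss (steepest negative NC slope) —
the connectivity/robustness trade-off the stability panel is designed to
expose.

The same analysis is available as a library — sklearn-style estimators
(`PrevalenceFilter`, `RelativeAbundance`, `RMTCorrelationNetwork`) compose
with sklearn pipelines, and every stage is also a plain function
(`prevalence_filter`, `correlate`, `rmt_threshold_scan`, `build_network`,
`detect_modules`, `zi_pi`, `keystone_sets`, `natural_connectivity`,
`cohesion`, `random_removal_curve`, `targeted_removal`, ...).

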