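# Methods

This note records the models, numerical choices and limitations behind
`micronet`, in the order the pipeline runs.

## Input model and filtering

The unit of analysis is an integer ASV × sample count table with a sample →
group map; each group's samples are analysed as an independent network (the
default; `filter_per_group=False` filters once across all samples instead,
for designs where a shared node universe across groups is wanted).

A taxon is retained when at least `ceil(min_prevalence · n_samples)` samples
contain it at `min_count` or more reads (defaults 20% and 4). The two
parameters are deliberately independent: "present" is defined by the count
floor, prevalence by the fraction of samples. The ceiling makes the
prevalence cutoff a true lower bound. Filtering is monotone (raising either
parameter never adds taxa) and idempotent; both properties are tested.

Before correlation, counts are transformed to log-relative abundances
ln(count/depth + pseudocount). The pseudocount defaults to 1e-6;
zero counts therefore map to ≈ ln(1e-6), a hard floor that is visible in
the correlation structure of rare taxa (see *Limitations*).

## RMT threshold selection

Pairwise Pearson correlations (Spearman optional) are computed across
samples; zero-variance taxa are flagged and assigned r = 0 off-diagonal.
For each cutoff *t* on a grid (default 0.30–0.95, step 0.01), entries with
|r| < *t* are zeroed, all-zero rows dropped, and the eigenvalues of the
truncated similarity matrix are tested for Poisson spacing statistics:

* **Unfolding.** A cubic smoothing spline is fitted to the eigenvalue ECDF,
  with smoothing chosen by a generalized-cross-validation grid whose
  effective degrees of freedom are capped at ~20. The cap matters: the fit
  must capture only the global spectral density — an interpolating fit
  would rescale every spacing to 1 and erase exactly the fluctuations the
  NNSD measures. Unfolded positions n·F(λ) are forced monotone and their
  first differences rescaled to mean spacing 1.
* **Goodness of fit.** The spacing histogram (ceil(√n) bins, open upper
  tail) is tested by χ² against the exponential density e^(−s) (Poisson)
  and the Wigner surmise (πs/2)e^(−πs²/4) (GOE); p-values come from
  χ²(bins − 1). A spectrum needs ≥ 20 eigenvalues — below that, spacing
  statistics are meaningless, and thresholds keeping fewer taxa are skipped.

The chosen threshold is the smallest *t* with p_Poisson ≥ α (default 0.05)
that keeps ≥ 20 non-isolated taxa. If no cutoff reaches Poisson statistics
the scan falls back to the argmax of p_Poisson with a warning; if no cutoff
keeps 20 taxa it raises. Both χ² statistics are reported per threshold so
the decision rule can be audited or replaced.

The network keeps both correlation signs: edge sign = sign(r), weight = |r|,
and isolated taxa are excluded from the node set (so "total nodes" counts
connected taxa, matching the usual reporting convention).

## Topology, modules, roles

All topology metrics use the unsigned, unweighted skeleton; signs are
consumed only by cohesion and edge reporting. Mean path distance averages
over *connected* pairs only — with disconnected components, counting
unreachable pairs as 0 would understate distances exactly where networks
are most fragmented. Modules come from deterministic greedy (CNM)
modularity maximisation (via networkx); module ids are ordered by smallest
member node so repeated runs are identical, and Q is cross-checked in the
tests against an independently coded Newman sum Σ_m (e_mm − a_m²).
Alongside the raw module count the pipeline reports *major* modules
(≥ 5 members), the usual convention for module-based role analysis; tiny
fragments of 2–4 background nodes are not modules in the Zi–Pi sense.

Z_i standardises within-module degree with the module's sample (ddof = 1)
standard deviation and is 0 where the module has no degree variance;
P_i = 1 − Σ_s (κ_is/k_i)², 0 for isolated nodes. Role cutoffs are the
standard Z = 2.5, P = 0.62 quadrants (configurable). Keystone sets: the
union of non-peripheral roles, and the ceil(0.1·n) highest-degree nodes
with ties broken by node id.

## Stability panel

* **Efficiency/vulnerability.** E = (1/(n(n−1))) Σ 1/d(i,j) with 1/∞ = 0
  for disconnected pairs; that convention is what makes V = 1 when a cut
  vertex shatters the graph. E_i is normalised by the reduced node count
  (n−1) — verified against the 3-path worked example (E = 5/6, removing
  the middle node gives V = 1).
* **Natural connectivity.** λ̄ = ln((1/N) Σ e^{λ_i}) on the unsigned 0/1
  adjacency, via log-sum-exp. It is 0 for edgeless graphs and strictly
  decreases under any edge deletion (tested exhaustively on all connected
  graphs with ≤ 6 nodes).
* **Cohesion.** Pairwise Pearson correlations of relative abundances are
  corrected by subtracting their mean under taxon-wise independent
  shuffles; the corrected matrix is split by sign into per-taxon positive
  and negative connectedness, and per-sample cohesion± is the
  relative-abundance-weighted sum. Two null-model details matter and are
  deliberate: the null correlation corr(observed_i, shuffled_k) is kept
  asymmetric (symmetrising halves the null variance and makes the
  permutation envelope spuriously tight), and the shuffled community is
  re-closed to unit sum per sample so the null carries the same
  compositional constraint as the data. The Neg:Pos ratio defaults to the
  mean over samples of |negative|/positive (samples with non-positive
  positive cohesion are excluded and flagged); the ratio of means is also
  reported.
* **Robustness.** Random removal: for each fraction f in 0–0.5 (step 0.05)
  and each of 100 replicates, round(f·n) nodes are removed in a fresh draw
  (fractions are independent, not nested — unbiased per-fraction means),
  and natural connectivity and average degree of the remainder are
  averaged; slopes are OLS against f. Targeted removal reports, for a
  keystone set, the mean percent decline over single-node removals from
  the intact network (MDP) and the percent decline after removing the
  whole set at once (TDP); for singleton sets the two coincide by
  definition. Declines may be negative — removing an isolated or
  low-degree node raises average degree.

## Synthetic community generator

The generator emulates a grouped amplicon survey: defaults are 3 groups of
6 samples, 300 taxa with 3 signal modules of 40, sequencing depth 10,000
reads/sample, gamma-multinomial (negative-binomial marginal) overdispersion
with shape 5, and log-abundance baseline spread of 1 (natural-log units).

Per sample j, module m draws a factor f_mj ~ N(0,1); member i has
log-abundance μ_i + ℓ_i f_mj + σ ε_ij. Loading magnitudes are
Uniform(0.5, 1.1) except one designated hub per module at 1.5, which also
receives its module's largest baseline μ: the designed hub is meant to be
a *detectable* keystone target, not one hidden at the detection limit. A
`neg_edge_fraction` of members (default 0.3) get negative loadings,
creating negative within-module correlations. σ is solved numerically
(Brent) so the mean within-module |Pearson r| of the *latent
log-abundances* equals `within_module_corr`; the latent matrix is exposed
in the ground truth so structure-recovery questions can be separated from
count noise. Background taxa are independent log-normals. Counts are
multinomial at fixed depth on softmax log-abundances with per-cell gamma
multipliers (preserving depth while adding NB-marginal overdispersion).
Ground truth: all within-module pairs are true edges with sign
sign(ℓ_iℓ_k); hubs as above.

What the generator does *not* emulate: sequence-level error, taxonomic
structure, sample-to-sample depth variation, and — importantly — sparse
rare-taxon zero inflation beyond what fixed-depth multinomial sampling
produces. Two realistic effects that it *does* reproduce shape the tests:
count-realisation noise attenuates latent correlations (a latent 0.75
within-module correlation realises around 0.5–0.6 in log counts), and
compositional closure couples taxa that are independent in latent space.
Because of the closure coupling, the count-space "background" is not a
clean null, and threshold-recovery checks are run on the latent layer,
where the background-iid premise holds exactly; the scan's chosen cutoff
there tracks the realized upper edge (99th percentile) of the null
correlation distribution to within a few hundredths. Passing tests
therefore demonstrate recovery of designed structure under idealised
grouped-count conditions, not performance on real soil data.

## Problem sizes and determinism

The test and acceptance workloads use 120-taxon, 30-sample communities
(3 modules of 20 + 60 background), 10-seed medians for recovery checks,
200 permutations for cohesion nulls and 100 replicates for removal curves
— sizes at which every quantity is stable yet the full suite runs in a
couple of minutes. All randomness flows from explicit integer seeds
(per-stage derived in the pipeline), and identical config + seed
reproduces every artifact byte for byte; the run manifest records config
hash, seed and package version.

## Known limitations

* Correlation + thresholding is not a compositional network-inference
  method (no SparCC/SPIEC-EASI-style corrections); closure-induced edges
  are possible, especially in small communities where a few taxa dominate.
  The same closure sensitivity means cohesion's permutation calibration is
  exact only for communities large enough (~hundreds of taxa) that no
  single taxon carries a large share.
* The NNSD decision needs ≥ 20 non-isolated taxa; very sparse or very
  small matrices fall back with warnings rather than silently choosing a
  cutoff.
* With ~6 samples per group (the default grouped design), null
  correlations are broad and chosen thresholds land high (0.7+); single
  networks at such sample sizes are reproducible but individually noisy —
  comparisons across groups are the intended use.
* Shortest-path metrics treat edges as unweighted; a weighted variant of
  the spectral metrics is exposed only through the unsigned default.
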