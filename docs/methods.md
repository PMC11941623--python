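# Methods

This note records the models, estimators and numerical choices behind
`coexdiff`, what the synthetic generator does and does not emulate, and the
design decisions that were genuinely open.

## Synthetic two-cohort generator

The generator exists because cohort-level human brain RNA-seq is
controlled-access: it provides a *stated world* in which every downstream
stage has recoverable ground truth.

**Model.** Gene g in sample s has negative-binomial mean

    mu[g,s] = L_s * exp(log_mu_g + rho * z[m(g),s] + delta_g * x_s) / Z_s

- `L_s`: library size, log-uniform over `libsize_range` (default 1e6–2e6
  reads; the spread forces non-trivial TMM factors).
- `log_mu_g ~ U(0, 4)` (natural log): ~55-fold dynamic range of baseline
  abundance, a modest but realistic spread for a filtered expression matrix.
- `z[m,s] ~ N(0,1)`: one latent factor per planted module, shared by the
  module's genes with loading `rho` (default 0.5). One shared factor per
  module is the simplest mechanism that yields block-structured
  co-expression with a single recovery-difficulty knob.
- `delta_g`: planted log fold change (natural log of the stated log2 value),
  applied to the late-cohort indicator `x_s`. A fraction `de_fraction` of
  genes, evenly spaced along the gene list, gets ±`de_log2fc` with
  deterministically alternating sign so expected up/down counts are exact.
  Separately, the genes of the first `n_perturbed_sets` planted annotation
  terms get a coherent +`de_log2fc` shift — these are the gene-set-level
  ground truth (an alternating-sign module would be invisible to a
  directional set test).
- `Z_s` renormalizes the per-sample means to the library scale, so planted
  fold changes are compositional, as in real sequencing.
- Counts are NB with dispersion `phi` (variance mu + phi·mu²; phi = 0 gives
  Poisson). Default phi = 0.1, a typical bulk RNA-seq value for human
  cohort data.

Cohort sizes default to 47 early / 174 late (diagnosis age below / at-or-
above 70 years), mirroring the motivating study's imbalance.

**What it does not emulate:** batch effects, cell-type composition shifts,
gene-length effects, realistic marginal distributions of brain tissue, or
annotation with hierarchical (DAG) structure. A green recovery test
establishes that the pipeline recovers planted structure under NB sampling
noise and library-size variation — not that it is robust to those
unmodelled features.

**A caveat the generator makes visible:** genes sharing a latent factor have
*correlated* fold-change noise, so unperturbed module-copy terms can reach
extreme gene-set q-values for any two-group split. This is the well-known
anticonservativeness of group-mean set tests under inter-gene correlation;
the calibration tests therefore use independent-gene null sets, and the
perturbed-set recovery test checks decoys, not module copies.

## Normalization and differential expression

**TMM.** For sample k against reference r, over genes positive in both,
M_g = log2((y_gk/N_k)/(y_gr/N_r)) and A_g = ½ log2((y_gk/N_k)(y_gr/N_r));
the top/bottom 30% by M and 5% by A are discarded and the factor is
2^(Σw_g M_g / Σw_g) with precision weights
1/w_g = (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr). The reference is the
sample whose upper-quartile CPM is closest to the mean of those quartiles
(the standard convention). Factors are recentred to geometric mean 1. The
implementation agrees with the Bioconductor edgeR `calcNormFactors` oracle
to ~1e-14 on random NB matrices (tested).

**Dispersion.** A single common phi by the method of moments: per gene and
group, (s² − μ̂)/μ̂² on counts rescaled to the geometric-mean effective
library, pooled over genes with (n−1) weights and floored at 0. This is a
deliberate simplification of likelihood-based tagwise shrinkage: it is
unbiased to within O(1/n) when a common dispersion holds (recovering
phi = 0.2 within ±0.01 at 2000×50, tested), which is sufficient for the
pipeline's comparative purpose. It will under-serve data with strongly
gene-specific dispersions.

**Exact test.** Counts are linearly rescaled to the common (geometric-mean)
effective library — a simplification of quantile pseudo-count adjustment —
and rounded; group sums S₁, S₂ are treated as NB with means nᵢμ̂ and
dispersions phi/nᵢ (the exact distribution of an iid NB sum). Conditional on
the total t, the two-sided p-value is the total conditional probability of
all splits no more likely than the observed one (minimum-likelihood method;
ties included with a 1e-10 log tolerance). With phi = 0 and one sample per
group this reduces exactly to the two-sided Binomial(t, ½) test. log2 fold
changes use group means with a prior count of 0.5 per group (no infinities);
orientation is fixed late-over-early and recorded in the table metadata.
Under the stated global-null world (phi = 0.1, 47 vs 174, 10000 genes) the
rejection rate at p < 0.05 is ~0.046 (tested to lie in [0.03, 0.07]).

**BH.** Step-up q_(i) = min_{j≥i}(m·p_(j)/j), capped at 1, returned in input
order; cross-checked against statsmodels.

**Filtering.** CPM ≥ 1 (raw library sizes) in at least min(cohort sizes)
samples, boundary inclusive. The rule is a documented convention — the
standard practice this pipeline assumes rather than a result.

## Gene-set enrichment on fold changes

Per-gene fold change is the difference of cohort means of log2 CPM (prior
count 0.5, library-scaled). Each set is compared to the all-gene background
(set included — the original method's convention; an exclusive background is
available) with the Welch t statistic; p_up/p_down are the upper/lower tail
probabilities, BH-adjusted per direction. A one-on-one sample-pairing mode
(each late column against the fold-change frame's columns, Stouffer-combined)
is exposed because the group-mean vs pairing choice is not fixed by the
problem; group-mean is the default.

## Mutual-information networks

- **Discretization:** equal-frequency bins, `n_bins = floor(sqrt(n_samples))`
  (the common default of MI network packages); rank-based with stable-order
  tie breaking; constant genes collapse to one bin (MI ≡ 0).
- **Estimator:** plug-in (maximum-likelihood) MI in bits. The pairwise
  computation is blockwise: for each bin pair the joint counts over all gene
  pairs are one matrix product, and Σ n·log₂n is a table lookup, so the full
  g(g−1)/2 sweep is BLAS-bound. A Miller–Madow small-sample correction is
  available behind a flag but off by default (the percentile threshold is
  rank-based, and the correction is rank-preserving only across equal
  marginal patterns).
- **Threshold:** the 99th percentile (linear interpolation between order
  statistics) of *all* pair values of each cohort separately; ties kept
  inclusively (an all-equal distribution keeps everything). Edge counts at
  the 1% tail are sensitive to the interpolation rule, hence it is pinned
  and recorded in the network provenance.
- **Significance:** per-edge p-values from G = 2·n·ln2·I ~ χ² with
  (r−1)(c−1) df. They are provenance only — filtering is by percentile, and
  at n = 174 with 13×13 bins the retained edges sit far below p = 1e-30,
  which is why percentile and significance filtering coincide in practice.
- MI is computed on log-CPM by default (configurable); whether to use
  counts, CPM or log-CPM is not fixed by the method, and rank-based
  discretization makes the choice matter only through tie patterns.

## Map-equation modules

Two-level map equation; undirected flow, so visit rates are exactly
strength/(2W) and no teleportation is needed. The optimizer is Louvain-style:
greedy single-node moves to neighbouring modules (accepted when ΔL < −1e-10
bits; ties broken toward the lowest module id for determinism), module
aggregation, repeat; `n_trials` independent random node orders (default
1000, matching the intent of "run many iterations to ensure convergence"),
best L kept. The local-move inner loop is numba-compiled; the ΔL uses the
decomposition L = plogp(q) − 2Σᵢplogp(qᵢ) + Σᵢplogp(pᵢ↻) − Σ_α plogp(p_α),
whose last term is partition-independent.

Properties verified by test: exact agreement with brute-force enumeration
over all set partitions on 50 random graphs of ≤ 7 nodes; NMI ≥ 0.9 on
4×25 planted-partition graphs; never worse than the single-module baseline;
codelength no worse than igraph's Infomap on modular graphs. Isolated nodes
carry no flow and are dropped with a warning before optimization;
disconnected components are handled naturally (cross-component merges never
lower L). A completely edgeless network is returned as one module at L = 0.

Only the flat two-level map equation is implemented — module counts are the
observable of interest, not hierarchy.

## Module enrichment and the bipartite network

Upper-tail hypergeometric p-values are summed directly from pmf terms
(1 − cdf loses all relative precision in small tails; direct summation
agrees with exact rational enumeration to 1e-12 relative for N ≤ 30,
tested). The universe is the set of genes in the analyzed network (the
conservative choice; the whole genome would inflate significance), catalogue
terms are intersected with it, modules below 10 genes are skipped (tiny
modules give unstable enrichment), and BH is applied jointly across all
module×term tests (one family; a per-module alternative exists behind a
flag). The bipartite graph keeps modules and terms with at least one
q < 0.05 edge, with a `layer` node attribute for export.

## Degree-distribution comparison

The two histograms are aligned on the union of observed degrees, then sparse
bins (expected count < 5, the classical validity rule) are merged with their
neighbour starting from the high-degree tail. Pearson χ² on the resulting
2×B table with df = B−1, upper-tail p, and Cramér's V = √(χ²/(n_total·1)).
If pooling collapses to a single bin the comparison is reported as null
(χ² = 0, V = 0, p = 1). V = 1 is attained exactly for fully separated
equal-size two-bin histograms (tested closed form).

## Pipeline

One master seed spawns independent per-stage seeds (numpy SeedSequence), so
the whole run — including the 1000-trial optimizer — is bit-reproducible.
Each cohort's network is inferred and thresholded on its own samples and MI
distribution; DE and gene-set enrichment use both cohorts. All artifacts are
plain text (TSV / GMT / GraphML / JSON / MatrixMarket) and the run report
contains only numbers re-derivable from them (tested).

## Known limitations

- Common (not tagwise) NB dispersion; no GLM/quasi-likelihood framework and
  no batch covariates.
- The exact test's library equalization is linear scaling, not full quantile
  adjustment; at strongly unequal library sizes the conditional NB sums are
  an approximation (empirically calibrated at the stated world's 2x library
  spread).
- Group-mean gene-set testing is anticonservative under inter-gene
  correlation (see the generator caveat above).
- The MI percentile threshold fixes edge *count*, not edge confidence; two
  cohorts with different sample sizes have systematically different MI
  scales (visible as different thresholds in bits), which is intrinsic to
  the design being emulated, not a defect of the estimator.
- Annotation terms are flat sets; no ontology DAG propagation.
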