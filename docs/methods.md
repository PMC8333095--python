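# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
cohort does and does not emulate.

## Normalization and variance stabilization

Sequencing depth differs between donors, so raw counts are scaled by
per-sample **size factors** estimated with the median-of-ratios scheme: a
reference pseudo-sample is the per-gene geometric mean over samples,
restricted to genes with no zero count anywhere, and sample *j*'s factor is
the median over reference genes of `count_gj / geomean_g`. For columns that
are exact scalar multiples of one another this recovers the scalars with
geometric mean 1; for noisy data the median makes the estimate robust to a
minority of genuinely differential genes (which is why the planted cluster
block in the synthetic cohort, 224 of ~4,000 genes, does not bias the
factors).

Counts are then placed on a log2-like variance-stabilized scale with the
shifted-log transform

    y_gj = log2(count_gj / s_j + 1).

This is a deliberate, deterministic stand-in for model-based
variance-stabilizing transforms: it is monotone and invertible per sample,
behaves like `log2` of normalized counts for well-expressed genes, and needs
no dispersion fit. All downstream statistics only require a log2-like
stabilized scale, not a particular VST family. The pseudocount (default 1)
is recorded on the `NormalizedMatrix` so fold changes can linearize values
exactly back to `count / s_j`.

**Expression filter.** A gene is removed iff its mean transformed value is
strictly below the threshold (default 4, i.e. ~15 normalized counts) in
*every* sample group. The grouping is an explicit argument — the pipeline
uses sex by default — because any factor-level grouping is defensible and
the choice only matters for genes straddling the threshold. The filter is
idempotent and the "below" is strict, so a mean of exactly 4 is kept.

**Depth QC** precedes normalization: samples with fewer than 100,000 total
reads (strictly) are dropped.

## Per-gene contrasts

Fold changes are ratios of arithmetic group means of linearized expression
(`2^y − 1`, floored at 0, which equals `count/s` exactly); the alternative
`2^(Δ mean log2)` is exposed as `mode="log"` since "mean-based" admits both
readings. A zero denominator yields `+inf`, never an exception.

Group tests are two-sided Welch (unequal-variance) t-tests on the
transformed values with Benjamini–Hochberg adjustment across all tested
genes (the BH step-up is delegated to statsmodels and cross-checked in the
test suite against a from-definition implementation). Degenerate genes —
zero variance in both groups — get `p = 1` when the means agree and `p = 0`
with a warning flag when they differ; the flag column records which
convention fired.

Age association is the per-gene Pearson correlation with donor age, with
t-distributed two-sided p-values and BH adjustment. Constant genes have no
defined correlation; they are reported as missing and excluded from the BH
family size rather than coerced to zero. |r| > 0.3 marks the "notable" band
used for reporting.

## Clustering

Donor vectors are clustered on Euclidean distances over all retained genes
(a top-variance subset is deliberately not the default: with ~4,000 genes
the distance geometry is already dominated by the informative block).
Linkage is Ward D2: the Lance–Williams recurrence on squared distances with
square-root merge heights, so heights are monotone nondecreasing; on the
worked 1-D example (0, 1, 10) the merges sit at 1 and √(361/3). The
implementation delegates to SciPy's Ward linkage (nearest-neighbor chain),
which is deterministic; exact distance ties are resolved by the chain order
rather than by lexicographic pair, which matters only for exactly tied
merges and is verified against an independent from-definition implementation
to 1e−9. Cluster labels after a k-cut are renumbered by first leaf
occurrence so output is stable.

The two-cluster contrast reports the genes at ≥ 4-fold (either direction)
between clusters, the fraction of genes under 2-fold, and counts at ≥ 3- and
≥ 4-fold. The cluster with the higher expression over the selected gene set
is called "hot" and placed in the numerator.

## Multivariate sample-vector tests

All three tests operate on the Euclidean distance matrix between donor
vectors and use relabelling permutations with group sizes fixed. Before any
computation the samples are put in canonical (sorted-ID) order, so p-values
do not depend on input column order. When the number of distinct labellings
`C(n, n_A)` is at most 20,000 the tests enumerate all of them and the
p-value is exact; otherwise `n_perm` labellings are sampled and the add-one
estimator `(b + 1)/(n_perm + 1)` is used, which can never return 0 — an
extremely strong effect reports the permutation floor `1/(n_perm + 1)`.
Default `n_perm` is 10,000. Per-comparison seeds in the battery derive
deterministically from the run seed.

**Minimum spanning tree.** Kruskal on the complete distance graph with
edges inserted in lexicographic node-pair order, so equal-weight ties are
deterministic. Optimality is verified in the tests against exhaustive
spanning-tree enumeration for n ≤ 6.

**Runs test (Wald–Wolfowitz generalization).** Statistic
`R = 1 + #mixed MST edges`; small `R` indicates separation, so the p-value
counts permuted labellings with `R' ≤ R`. `R` is a small integer with heavy
ties, which makes the plain permutation test noticeably conservative at
cohort sizes of a few dozen donors. Exceedance counting therefore refines
ties with a continuous secondary criterion: among labellings with equal
`R`, those whose mixed edges have larger total weight count as more extreme
(two distant clouds connect through long bridge edges). The reported
statistic is still `R`, exact enumeration results on small fixtures are
unchanged, and the refinement brings the achieved level back to the nominal
one (verified by simulation in the test suite).

**MST–KS test.** The tree is rooted at a node of maximal hop eccentricity
(ties to the smallest index) and donors are ranked by depth-first preorder
with children visited in decreasing subtree-height order, ties again to the
smallest index — a deterministic variant of the ranking family used by
graph-based two-sample tests; alternative rankings can be swapped in. The
statistic is `D = max_k |F̂_A(k) − F̂_B(k)|` over rank prefixes, and the
p-value counts `D' ≥ D`. `D` lives on a grid of multiples of
`1/min(n_A, n_B)`, so ties are refined by the mean prefix discrepancy, with
the same rationale and verification as for the runs test.

**Similarity test.** Group similarity is the median of reciprocal
within-group pairwise distances — higher means a tighter group. Duplicate
donor vectors (zero distance) make the reciprocal undefined and are a hard
error naming the pair. The test statistic is the difference of the two
group similarities and the test is two-sided on its absolute value; the
choice of two-sided is the conservative reading of "testing the difference
between median similarities".

**Battery.** For each factor — sex; age in decade-style bins (≤30, 31–40,
41–50, 51–60, >60), a three-way division (≤40, 41–60, >60), and a median
split at 42.5 years; storage time (<12 h vs ≥12 h); the Ward cluster
assignment; and library-size tertile — every pairwise comparison runs all
three tests. The significance threshold is α = 0.05, Bonferroni-divided by
the number of pairs only for the library-size factor (3 pairs → 0.0167),
mirroring how such batteries are conventionally reported; the set of
Bonferroni-corrected factors is an argument. Factor levels with fewer than
2 samples are skipped with a warning.

## Synthetic cohort generator

The generator is a stand-in for a real healthy-donor cohort, not a fitted
model. Counts follow a negative-binomial model
`NB(mean = b_g · e_gj · d_j, dispersion α)` with:

* `b_g` — baseline mean: ~`n_genes_retained_target` "main" genes with log2
  abundance `4.3 + Exponential(1.3)` capped 10.4 above the floor (so the top
  transcript holds a few percent of the library, never most of it), scaled
  so the expected library size matches the configured mean (default
  811,858 reads); plus a low tail (default 1,000 genes) with absolute mean
  counts `2^U(−3, 3.2)`, safely below the expression filter.
* `d_j` — per-sample depth, log-normal with σ = 0.35, centred to mean 1.
* `α` — gene-wise dispersion, default 0.05 (counts CV ≈ 22% beyond Poisson),
  a realistic overdispersion for bulk RNA-seq; no dispersion estimates exist
  for the emulated cohort, so this is a configurable assumption.

Donor covariates: 119 female / 85 male (shuffled), ages truncated-normal
mean 42.11, SD 13.89 on [18, 86], storage <12 h for 80% of donors, a
9-donor secondary collection site, and library-size tertile labels computed
from the realized totals.

Planted effects (all multiplicative on the NB mean, all echoed in the truth
record):

* **Sex gene** — one well-expressed gene scaled by fold change 2.10 in
  males.
* **Age gene** — log2 mean linear in age. The slope is calibrated
  analytically so the *expected* Pearson correlation on the transformed
  scale equals the target (0.409): the noise SD of `log2(count/depth + 1)`
  is computed exactly from the NB pmf integrated over the depth
  distribution with Gauss–Hermite quadrature, and the realized
  (truncated-normal) age SD is used. Verified unbiased at large n; at
  n = 204 the estimate carries the usual `(1 − r²)/√n ≈ 0.06` sampling
  error.
* **Cluster block** — donors split 50/50 into two clusters; 224 genes are
  up-scaled in cluster 2, 218 with fold changes log-uniform in ≈ [4.5, 9.5]
  and 6 extreme genes in ≈ [11, 22]. The draws keep a ~12% margin inside
  the 4-fold and 10-fold classification boundaries so that planted genes
  remain separable from unplanted ones under sampling noise — without the
  margin a gene planted at exactly 4.0-fold is a coin flip against the
  measured 4-fold threshold and "recovery" would be ill-posed.
* **Storage shift** (off by default) — applied to a random half of the
  transcriptome rather than globally, because a truly global multiplicative
  shift is exactly a depth change and is removed by size-factor
  normalization.

Planted genes are drawn from the 70th–97th abundance percentile of the main
genes: expressed well enough for stable group means, below the saturated
top.

**What the generator does not emulate:** splice-junction read structure,
alignment artifacts, leukocyte contamination, gene–gene correlation beyond
the planted block, batch effects on composition, and the long intermediate
fold-change spectrum of real cohorts (unplanted genes are null, so summary
quantities such as "fraction of genes under 2-fold" come out higher than in
real data). Tests passing on this cohort demonstrate that the *methods*
recover known structure under realistic count noise, not that real platelet
data has that structure.

## Problem sizes and runtime choices

Calibration studies use 500 replicates of 40-donor, 300-gene null cohorts
with 199 permutations per test — large enough that a miscalibrated test
would be flagged (binomial SE ≈ 0.01 on a 0.05 rate) while the whole study
runs in seconds; the per-gene t-test level is checked on 2,000 null genes.
Effect recovery runs at the full default scale (204 donors, ~5,000 genes).
Pipeline determinism is demonstrated on a 60-donor cohort with 99
permutations; determinism is structural (seeded generators, fixed float
formatting) and does not depend on problem size.

## Known limitations

* The shifted-log transform under-stabilizes variance for genes near the
  expression filter; statistics there are noisier than a model-based VST
  would give.
* The battery's p-values for the cluster factor inherit the usual
  post-selection caveat when the cluster labels were derived from the same
  matrix; the battery accepts any labelling and does not correct for this.
* Exact enumeration switches on a labelling-count cap (20,000); p-values
  just above and below the cap are estimated with different (exact vs
  Monte Carlo) resolution.
* The runs and MST–KS tests use documented tie-break refinements; a purist
  implementation without them reports the same statistics but is
  conservative at small n.
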