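# platelet-landscape

Analysis pipeline for the variability of the blood-platelet transcriptome in
healthy donors. Platelets carry a rich, stable RNA repertoire, and deviations
from the healthy baseline are diagnostically informative (for example in
tumor-educated platelets), so the question this package addresses is: how much
does the healthy platelet expression profile vary with sex, age, blood storage
time, collection site, and sequencing library size — both transcript by
transcript and when each donor is treated as a single multivariate expression
vector?

The package provides, as a tested library plus a thin CLI:

* **Preprocessing** of spliced-read count matrices: depth QC (samples under
  100 k reads excluded), median-of-ratios size factors, a shifted-log
  variance-stabilizing transform `log2(count / s_j + 1)`, and removal of genes
  with mean log2 expression below 4 in every sample group.
* **Per-gene contrasts**: mean-based fold changes, Welch t-tests with
  Benjamini–Hochberg FDR, Pearson correlation with donor age, and top-N
  ranking overlap.
* **Unsupervised structure**: Ward D2 hierarchical clustering of donor
  vectors on Euclidean distances, a two-cluster cut, and fold-change
  thresholded contrasts between the clusters.
* **Multivariate sample-vector tests** on the minimum spanning tree (MST) of
  the donor distance graph:
  * the multivariate Wald–Wolfowitz runs test — statistic
    `R = 1 + #(MST edges joining differently labelled donors)`, small `R`
    meaning separated groups;
  * an MST–Kolmogorov–Smirnov test of multivariate means — donors are ranked
    by a deterministic depth-first traversal of the MST and
    `D = max_k |F̂_A(k) − F̂_B(k)|` compares the groups' cumulative membership
    along that ranking;
  * a within-group similarity test — each group's similarity is the median of
    `1/d_ij` over all within-group Euclidean distances, and the difference of
    group similarities is tested against its permutation distribution
    (10,000 relabellings by default).

  All p-values are permutation p-values with group sizes fixed, using the
  add-one estimator `(b + 1)/(n_perm + 1)`; small label spaces are enumerated
  exhaustively and give exact p-values. A test battery runs all three tests
  for every factor (sex, three age groupings, storage time, cluster, library
  size) with Bonferroni thresholds for multi-pair factors.
* **A synthetic cohort generator**: negative-binomial counts for 204 donors
  (119 female / 85 male, ages truncated-normal 42.11 ± 13.89 within 18–86,
  mean library size ≈ 811,858 reads, ≈ 3,954 well-expressed transcripts) with
  planted effects — one sex-linked gene (fold change 2.10), one
  age-correlated gene (target r = 0.409), and a 224-gene two-cluster block at
  ≥ 4-fold of which 6 genes exceed 10-fold — plus a full truth record, so
  every stage of the pipeline is testable without external data.

## Worked example

```python
from platelet_landscape.synthetic_cohort import CohortConfig, generate_cohort
from platelet_landscape import preprocess, contrasts, clustering, vector_stats

counts, samples, truth = generate_cohort(CohortConfig(seed=0))
groups = samples.set_index("sample_id")["sex"]
norm = preprocess.preprocess_counts(counts, groups)

sex = contrasts.group_ttest(norm, groups, "male", "female")
corr = contrasts.age_correlation(norm, samples.set_index("sample_id")["age_years"])

dist = vector_stats.euclidean_distance_matrix(norm)
tree = clustering.ward_d2_linkage(dist.to_numpy(), list(norm.sample_ids))
cut = clustering.cut_tree(tree, 2)
cc = clustering.cluster_contrast(norm, cut, fc_threshold=4.0)
runs = vector_stats.ww_runs_test(dist, cut.astype(str), n_perm=10_000, seed=1)
```

prints (via the summary statements in the repository's example snippet):

```
retained 3954 of 4954 transcripts across 204 donors
sex-linked gene GENE03438: FC = 2.17, q = 1.09e-46
age-linked gene GENE03729: r = 0.404
two clusters of 102 and 102 samples; 224 genes at >= 4-fold, 224 at >= 3-fold, 94% of genes below 2-fold
cluster runs test: R = 2, p = 0.0001
```

Reading this: the expression filter keeps the 3,954 well-expressed
transcripts; the planted sex effect is recovered at fold change 2.17 (target
2.10) with a vanishing FDR q-value; the planted age correlation is recovered
at r = 0.404 (target 0.409); Ward D2 finds the two planted donor clusters
exactly and the 224-gene block separates them at ≥ 4-fold; and the runs test
collapses to `R = 2` (a single mixed MST edge), at the permutation floor
`p = 1/10001 ≈ 0.0001`.

The same analysis runs from the shell:

```sh
platelet-landscape run --simulate --out results/ --seed 0
platelet-landscape run --counts counts.tsv --samples samples.tsv --out results/
```

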