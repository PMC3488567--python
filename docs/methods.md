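# Methods note

This note records the statistical model behind `rcctriad`, the default
parameters, why they were chosen, and the known limitations. All defaults
are study conditions: they were fixed before the acceptance experiments
were run and are not tuned to any particular outcome.

## Clustering model

Samples and genes are clustered agglomeratively with **unweighted average
linkage (UPGMA)** on **Euclidean distances** of log2 intensities, the
classical combination for two-way heatmap displays of microarray data. No
row or column standardization is applied; values are clustered as-is on
the log2 scale. Trees are cut into exactly *k* clusters by undoing the
*k − 1* highest merges. Cophenetic distances (the merge height at which
two leaves first join) drive the cluster-naming heuristic.

Ties in the agglomeration are resolved by the linkage implementation's
ordering (SciPy), not by an explicit lexicographic rule; tests therefore
compare cophenetic matrices, which are invariant to sibling order.

## Pathway-anchored grouping

- `min_set_size = 150`: only gene sets well above ~150 members produce
  clearly distinguishable gene clusters; 20 is offered as a permissive
  exploratory threshold in the error message when nothing passes.
- Candidate representative clusters are *all* gene-dendrogram subtrees
  with between `min_cluster_genes = 5` genes and 80% of the set. Each is
  scored by the adjusted Rand index between (a) the k-cut of a sample
  clustering computed on the candidate's genes only and (b) a reference
  partition from clustering the full post-filter matrix. Up to
  `max_clusters_per_set = 4` disjoint candidates with positive score are
  kept, greedily by descending score. This replaces a visual "best
  represents the overall clustering" judgement with a monotone,
  reproducible criterion.
- `k_groups = 4` when cell lines are present (A/B/C + cell lines), 3 for
  tumor-only cohorts.
- **Naming.** Cluster letters are conventions. The cell-line cluster is
  the one with majority cell-line annotation. Among tumor clusters, B is
  the most distant in mean between-cluster cophenetic distance and, of
  the remaining two, A is the internally tighter cluster. Both are
  measured on a genome-wide sample dendrogram rather than the pooled
  signature's dendrogram, because B's distinctness and A's tightness are
  genome-wide observations. A user-supplied override map always wins.
- Stability re-clusters samples on `n_random_sets = 5` uniform random
  draws of `random_set_size = 660` genes (without replacement, seeded)
  and reports the adjusted Rand index of each against the assignment.

## Marker discovery (SAM-type)

Per-gene score `d = (mean1 − mean2) / (s + s0)` with `s` the pooled
standard error of the mean difference. The fudge factor `s0` defaults to
the **median of the per-gene standard errors** (`median_si`), a common
and robust simplification; a fixed value and a Tusher-style grid search
(minimizing the coefficient of variation of the d-spread across deciles
of `s`) are available. q-values come from class-label permutations
(default 100, capped at the number of distinct assignments): the median
null count of |d| exceedances divided by the observed count, clipped to
[0, 1] and monotonised so larger |d| never receives larger q. Marker
lists keep genes with fold change ≥ 2 (inclusive) in either direction,
ranked by |d|. Fold changes are differences of log2 class means, i.e.
they are ratios of geometric means on the natural scale.

## Constrained shuffle significance test

The null model preserves group sizes and, to make the null harder for a
grouping that could merely reflect histology, forces at least
`ceil(1/3 × |A|)` of group A's slots to be ccRCC-subtype samples
originally labelled B or C. Inside **every** shuffle, the full variable
selection pipeline is rerun — a random forest ranks all genes by impurity
importance, the top `n_top_variables = 4` are refit — so selection bias
is identical under null and observed labels. The empirical p-value is
add-one smoothed: `p = (#{shuffle ≥ original} + 1) / (n_shuffles + 1)`;
with 500 shuffles and zero exceedances, p = 1/501 ≈ 0.002.

**Test statistic: out-of-bag (OOB) accuracy**, not resubstitution
accuracy. A random forest's resubstitution accuracy saturates at ~1
regardless of labels, which would make the permutation test powerless;
OOB accuracy is an honest internal generalization estimate and is the
default error readout of the reference random-forest implementation.
Resubstitution and LDA accuracies are reported alongside for
completeness. Forest size defaults to 500 trees; the acceptance-scale
runs use 100 trees, which leaves the OOB gap between structured labels
(≈ 0.99 on the default synthetic cohort) and shuffled labels (≈ 0.55)
enormous while keeping a 500-shuffle run within minutes.

Calibration: on structure-free data the test is slightly conservative
(ties in OOB accuracy are counted against the observed labels), which is
verified empirically over 200 null datasets in the acceptance suite. It
is never anti-conservative there.

## Copy-number landscape

Segment means beyond ±0.13 (strict inequalities) are called gains or
losses; segments shorter than 100 kb are removed *first* as likely
germline copy-number variants. Calls project onto cytogenetic bands by
any ≥ 1 bp overlap; a band hit by both directions in one case is flagged
concurrent and counts toward both directions in cohort frequency
profiles. Focal analysis keeps called segments strictly below 5 Mb and
reports distinct (chromosome, start, end, direction) regions with
supporting cases and overlapping coding regions. All intervals are
handled 0-based half-open internally; 1-based inclusive SEG input is
converted on load.

## IHC rule and survival

The marker rule is a total function of three statuses: MVD high iff
count > 100 per 0.036 mm² spot, low iff < 50, otherwise indeterminate;
DEK/MSH6 positive iff > 1% nuclear staining. MSH6-negative → B (at any
MVD and DEK); high MVD + DEK+ + MSH6+ → A; low MVD + DEK+ + MSH6+ → C;
all other profiles — including indeterminate MVD and DEK−/MSH6+ — are
unassigned. DEK status deliberately does not veto B.

Survival uses the Kaplan–Meier product-limit estimator and the k-group
log-rank test (χ² with k − 1 degrees of freedom).

## Synthetic study generator

Defaults (one cohort = 97 primary tumors split 49/24/24 into A/B/C, 15
metastases cycling A/B/C, 34 cell lines; 2000 genes; baseline log2 level
7.0; i.i.d. Gaussian noise, SD 0.7):

- **B signature** (40 genes): two thirds up-shifted in B by
  U[log2 5.2, log2 14.4], one third down by U[log2 5.7, log2 8.7] — the
  published B-vs-rest fold-change ranges.
- **A-vs-C signature** (40 genes): 80% A-high, 20% C-high, magnitudes
  U[log2 4.2, log2 16]. The shift is split symmetrically (+δ/2 in A,
  −δ/2 in C) so the planted A−C difference is δ while B sits at baseline
  between them: B separates from both groups and A lies nearer C than B,
  reproducing the observed tumor-tree topology (A as a tight cluster
  within the C clade; asserted via cophenetic distances in tests).
- **Pathway-structured backdrop** (200 genes): each separates one group
  from the rest by a moderate shift (U[1, 2] log2, random sign), with
  group probabilities (0.2, 0.6, 0.2) biased toward B so that B is the
  most distinct group on any representative gene subset — the property
  the naming heuristic relies on — while A and C stay comparatively
  close.
- **Cell-line block** (80 genes, +2.0 in cell lines) makes cell lines
  cluster apart; **absent genes** (50) sit at a constant sub-detection
  level (1.0) while all expressed values are clipped at 2.0, so the
  absent-probe filter has an exact target.
- **Gene sets**: four 200-gene pathway sets each holding quotas of 10 B
  signature, 10 A-vs-C signature, 50 structured, 20 cell-line-block and
  110 background genes; three small background-only sets (30/60/100)
  exercise the size filter.
- **Copy number**: per-tumor event counts are Poisson with means
  (2, 5, 6) for A/B/C; events mix sub-100 kb decoys, sub-5 Mb focal and
  broad segments with |log2 ratio| in [0.2, 0.8], plus near-zero filler
  segments; the toy genome is 22 chromosomes × 100 Mb with 5 Mb bands.
- **Survival**: exponential with group medians (80, 45, 25) months under
  uniform censoring on [6, 120] months — best outcome in A, worst in C.
- **IHC**: 75% of tumors receive a profile matching their group's rule;
  the rest fall into genuine rule coverage gaps (intermediate MVD, or
  DEK−/MSH6+), so the assignable fraction lands near three quarters and
  assigned tumors always match their true group.

All generators are pure functions of the spec and seed; sub-generators
use fixed seed offsets so artifacts are independently reproducible.

## Limitations

- The synthetic cohort is far cleaner than a real microarray study: i.i.d.
  Gaussian noise, no batch effects, no probe-level artifacts, exact
  group-conditional shifts. Recovery at ARI 1.0 therefore demonstrates
  correctness of the machinery, not expected field performance.
- The cluster-naming heuristic assumes the B-most-distant /
  A-tighter-than-C geometry; on cohorts violating it, use the explicit
  override map.
- Cytoband logic is exercised on a uniform toy genome; real cytoband
  files (e.g. UCSC `cytoBand.txt`) load through the same reader but are
  not bundled.
- The permutation FDR uses the median null exceedance count (a common
  simplification) rather than the full SAM exchangeability machinery
  with quantile-matched permutation scores.
- The shuffle test's p-value resolution is 1/(n_shuffles + 1); with the
  default 500 shuffles the smallest attainable p is ≈ 0.002.
- No Cox regression, no multiple-testing control across contrasts, and
  no image-based IHC quantification.
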