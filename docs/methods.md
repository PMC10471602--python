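# Methods

## Problem and model

The pipeline treats gene expression variance among biological replicates as a
molecular readout of canalization. Counts for gene *g* in a sample of group
*k* (a cross-type × time-point combination; eight groups in the full design)
are modeled as negative binomial with mean s·μ_gk (s a per-sample library
size factor) and variance μ + φ_gk·μ², so the coefficient of variation is

    CV = sqrt(1/μ + φ).

The Poisson term 1/μ ties raw CV to expression level, which is why variability
must be compared between expression-matched genes (the LCV) rather than on raw
CVs, and why planted *variability* differences in the simulator act on the
dispersion φ rather than on means.

## LCV: sliding-window CV percentile

Per group, counts are normalized by median-of-ratios size factors (reference
genes = nonzero in every sample; library-size fallback otherwise), replicate
mean and sample SD (n−1) give the CV, and genes are ordered by mean
expression, ties broken lexicographically by gene id for determinism. For a
focal gene at rank r among n scored genes, the window is the `window_size`
(default 500) consecutive genes centred on r and clamped at the extremes, so
every percentile is computed over the same number of competitors. The focal
CV's ascending rank within the window (mean tied ranks) is rescaled as
100·(rank−1)/(window−1), which attains the documented endpoints: the least
variable gene in its window scores 0, the most variable 100. Zero-mean genes
have no defined CV; they are excluded from that group's ordering and reported
NA. If fewer defined genes than the window exist, the window shrinks to all
defined genes with a logged warning. The exact window centring and tie rule
are design choices; they are fixed, documented here, and pinned by an
exhaustive brute-force oracle in the tests.

Groups pool the three families within each cross-type × time point: the
variability statistic needs all nine replicates, and family structure is
carried in the metadata but not modeled at this stage.

## Clustering

Gene profiles (rows = genes, columns = group LCVs) are clustered with k-means
on raw LCV values — the scale is already bounded and comparable across
groups, so no row standardization. Lloyd's algorithm is written in-package
(seeded by scikit-learn's k-means++ initializer, best of `n_restarts` by
within-cluster sum of squares) so the objective can be asserted non-increasing
at every iteration; scikit-learn's KMeans serves as an independent check on
the achieved objective in the tests. Labels are renumbered by descending
cluster mean LCV for run-to-run stability. k defaults to 10, and a silhouette
scan (Euclidean, mean silhouette width, ties to the smallest k) is provided as
the verification step; a k whose fit degenerates to one cluster is reported
NA, and fully degenerate data yield no selected k rather than an error.

Heatmap export orders columns by average-linkage hierarchical clustering on
Euclidean distances between group LCV profiles (serialized as Newick via
scikit-bio) and rows by cluster, then by within-cluster leaf order. Distance
and linkage are conventions (the most common heatmap defaults) and are
recorded in the run manifest. Cutting the column tree into two clusters is
the package's operational check for the maternal-pairing signature: when
maternal patterns dominate, the two halves are exactly the PL-maternal and
SB-maternal groups.

## Per-cluster Bayesian linear model

Each cluster's LCV scores across groups form the response of a group-means
model y = μ_group + ε, ε ~ N(0, σ²), with conjugate priors: μ ~ N(0, c) with
c = 10¹⁰ (effectively flat) and σ² inverse-gamma parameterized by (V = 1,
ν = 0.002), i.e. shape ν/2 and scale νV/2 — a weakly informative residual
prior. The Gibbs sampler alternates exact conjugate draws of the group means
given σ² and σ² given the means; defaults (13,000 iterations, thinning 10,
burn-in 3,000) retain exactly 1,000 draws. Because the conditional draws are
nearly independent under this model, lag-1 autocorrelation of retained draws
is tiny; if it exceeds 0.1 a warning recommends the long settings
(130,000 / 1,000 / 3,000) appropriate for smaller, noisier datasets.

Point estimates are posterior modes: the argmax of a Gaussian KDE (Silverman
bandwidth) on a 512-point grid over the draw range. Intervals are 95% highest
posterior density: the shortest window of ⌈0.95·n⌉ order statistics, found by
exhaustive minimization — never longer than the equal-tail interval, and
shifted toward the mode on skewed posteriors. Two groups are called
distinguishable when their HPD intervals are disjoint; touching endpoints
count as overlap, a deliberately conservative rule (toward "no difference").
The model does not truncate at the LCV bounds, so HPD limits can slightly
exceed [0, 100] for clusters near the extremes; calls use overlap, not the
bounds, so this is cosmetic.

A fixed-σ² variant of the sampler exposes the Normal–Normal conjugate
posterior in closed form and anchors the validation tests.

## Differential expression and inheritance calls

Mean expression is compared with a deliberately simple, fully specified NB
GLM: genes with fewer than 10 total reads are removed; per-gene dispersion is
the pooled within-group method-of-moments estimate φ̂ = max(0, (s² − m̄)/m̄²)
on normalized counts, shrunk toward a fitted φ(μ) = a0/μ + a1 trend with
weight n/(n + n0), n0 = 5, floored at 10⁻⁸; each contrast is a log-link GLM
with group (and optional batch) design and log size-factor offsets; the Wald
statistic log2FC/SE is referred to the standard normal, and BH adjustment
(threshold 0.1) runs across converged genes only, so failed fits cannot
silently inflate the family size. Fold changes are unshrunk. At nine
replicates per group the normal-reference Wald test is mildly liberal — the
measured type-I rate on null NB data is ≈0.055–0.065 at a nominal 0.05 —
which is the expected finite-sample behavior of this estimator family and is
measured, not hidden, by the calibration test and the acceptance script.

Inheritance patterns are assigned by one deterministic rule cascade applied
at two levels. For mean expression (per gene), "significant" = adjusted
P < 0.1 in the relevant contrast and values are fitted means; for variability
(per cluster), "significant" = non-overlapping HPD intervals and values are
posterior modes. The cascade: over-/underdominant (mean level only: each
hybrid significantly beyond both pure crosses), maternal (each hybrid matches
its maternal pure cross and separates from the other, pure crosses distinct),
PL-/SB-biased (both hybrids match one pure cross), transgressive variability
(a hybrid's interval disjoint from and outside the span of both pure crosses,
in either direction), intermediate (strict betweenness with all four
hybrid–pure contrasts significant), conserved (no significant contrast),
otherwise ambiguous. The cascade is exhaustive and mutually exclusive by
construction, symmetric under relabeling the morphs, and every call carries
the evidence needed to re-derive it. Strict betweenness for "intermediate"
and the closed-interval overlap rule are the two places the evidence rules
were genuinely open; both choices are the conservative ones.

Overall dominance is tested by comparing DE-gene counts between a pure cross
and each reciprocal hybrid with the Yates-corrected 2×2 χ² (via scipy),
assuming the shared filtered gene set as a common denominator, and Bonferroni
control over the four comparisons (0.05/4 = 0.0125, reported as 0.013 with
half-away-from-zero rounding).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design exactly: 4 cross-types × 2 time
points × 9 replicates (3 families × 3 embryos) = 72 samples. Defaults, chosen
once as realistic bulk-RNA-seq conditions: 2,000 genes; log-normal baseline
means (natural-log mean 5, SD 1; median ≈ 148 counts); dispersion trend
φ = 3/μ + 0.05 (a standard decreasing mean–dispersion shape, giving the
level–variability coupling the LCV must correct); library-size factors
log-uniform on [0.7, 1.4] to exercise normalization; a ±2-fold time-point
shift on 30% of genes to mimic a strong developmental signal. Planted
effects: mean patterns shift group means by δ = 2 log2 units (fractions:
maternal 0.05, PL-/SB-biased 0.025 each, intermediate 0.05, over-/
underdominant 0.01 each); variability patterns scale group dispersions by
ρ = 4 (maternal 0.05, PL-/SB-biased 0.025 each, transgressive 0.05 split
between the two hybrids and both directions). Every pattern is planted in
mirror-image variants (which morph carries the high value; which hybrid and
direction for transgressive), recorded in the truth table — this balances the
planted load across groups so no cross-type is more variable by construction,
and gives recovery tests parameter-homogeneous gene sets. ρ and δ are harness
choices: the reference analysis reports no quantitative effect sizes for its
variability differences.

What the generator does **not** emulate: family-level random effects (families
exist only as labels), gene–gene correlation, batch structure in the counts
(the batch column is constant unless configured), miRNA-specific length/count
structure, and any genomic positional signal. Consequently, passing recovery
tests shows the statistical chain detects the planted signal under the
assumed NB model at the study's sample sizes — not that real data meet those
assumptions.

Recovery of planted variability patterns is evaluated on the truth table's
planted gene sets (one "cluster" per planted variant) rather than on
re-estimated k-means clusters: this isolates the inference-and-classification
chain, while k-means and the silhouette scan are validated separately on
separable fixtures. A known limitation of the rank-based LCV matters here:
because percentiles are zero-sum within a window, a group carrying many
inflated-dispersion genes slightly depresses the scores of its conserved
genes, so a large all-conserved cluster (very tight HPDs) can drift away from
a CONSERVED call as planted fractions grow. With the balanced mirror-image
variants above the effect largely cancels and the conserved cluster is
recovered at the default settings.

## Numerical and operational choices

- Determinism: every stochastic stage is seeded; per-cluster Gibbs seeds are
  derived from the stage seed and cluster label. Same seed + input ⇒
  bit-identical output.
- Mean-expression ordering ties (LCV) break by gene id; k-means labels
  renumber by descending cluster mean; BH preserves input order.
- Degenerate inputs: all-zero matrices, zero-margin χ² tables, < 2 defined
  CVs per group, and settings retaining < 100 draws are hard errors; zero-mean
  genes, shrunken windows, non-converged GLM fits and degenerate silhouettes
  are flagged/NA with logged warnings.
- Problem sizes in the test suite and acceptance script (2,000 genes, the
  full 72-sample design, one LCV run per check) were chosen so that each
  end-to-end property is measured on the full study design while the whole
  suite stays interactive (~1 minute).

## Known limitations

- The Wald test's mild liberality at n = 9 (above); users needing exact
  error control at this depth should prefer more replicates or permutation
  calibration.
- LCV percentiles are relative within a group: a genuine global change in
  variability affecting most genes in one group is invisible by design.
- HPD intervals are not truncated to [0, 100].
- The per-cluster model pools genes as exchangeable observations and ignores
  gene-level dependence within clusters; interval widths therefore scale with
  cluster size and should be read as precision of the cluster mean, not of
  any single gene.
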