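# Methods

This note documents the statistical procedures implemented in `stabsig`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish.

## Preprocessing

**Size factors.** Median-of-ratios: for sample j,
`s_j = median over usable genes of counts[g,j] / geomean_k(counts[g,k])`,
where a gene is usable iff it has a positive count in every sample (so its
geometric mean is positive). The median is taken in ratio space — with an
even number of usable genes this averages the two middle *ratios*, not
their logs. Factors are returned raw and rescaled to geometric mean 1; the
normalized matrix uses the rescaled factors. If no gene is positive
everywhere the operation fails with a pointer to the all-zero-row filter
rather than silently using a subset rule.

**Expression filter.** A gene is kept iff it has ≥ `min_count` (default 10)
reads in ≥ `min_sample_frac` (default 0.40) of samples. Both thresholds are
inclusive and the fraction is compared exactly (no rounding), which matters
when 40% of an odd sample count is fractional. The filter is idempotent and
monotone in `min_count`; both properties are tested.

**Batch stage.** The pipeline treats batch integration as a pluggable
stage on raw counts, ordered before normalization and filtering. Three
methods: `none`; `median-center`, which rescales each (gene, batch) block
so batch-wise gene medians match the global gene median (rounded to
integers, floored at 0) — a location alignment sufficient for the
downstream rank and correlation statistics; and `external`, a pass-through
contract for a matrix adjusted by a full empirical-Bayes tool run
elsewhere. Genes silent in a batch are left untouched there rather than
scaled by an undefined ratio.

## Signature derivation

**Correlation signatures.** Per gene, Pearson r of log2(normalized + 1)
expression against a continuous clinical outcome over samples with a
non-missing outcome; two-sided p from `t = r sqrt((n-2)/(1-r^2))` on n−2
df; |r| = 1 maps to p = 0; constant genes are skipped with a logged count.
Genes with r > 0 (r < 0) and p below the threshold form the positive
(negative) signature, ordered by ascending p then descending |r|. The
p-values are deliberately **unadjusted**: these thresholds are raw per-gene
screening cut-offs (0.05 for the month-6 and prevention-study analyses,
0.01 for the baseline new-onset analysis), not FDR-controlled discovery
sets; multiplicity control for this stage comes from the planted-null
calibration test (the false-positive fraction at p < 0.05 is ≈ 5%) and
from the downstream stability selection.

**Placebo exclusion.** A signature gene is dropped when its placebo-arm
correlation with the progression outcome has p < 0.05 in *either*
direction, since any such gene tracks disease progression rather than
treatment response. Survivor order is preserved. The threshold matches the
derivation threshold and is exposed as a flag.

**Cross-study intersection.** Same-direction signatures intersect on gene
id; the combined ordering is by mean of the two input ranks with
lexicographic ties.

**Wilcoxon signatures.** Two-group DE tests only genes detected (> 0) in
≥ 25% of either group; two-sided rank-sum p is exact (full enumeration via
the distribution of the U statistic) when both groups have ≤ 8 samples and
no ties, else a normal approximation with midranks, tie correction and
continuity correction; a rank-symmetric comparison (U equal to its null
mean) returns p = 1 exactly. Bonferroni multiplies by the number of genes
actually tested. Ranking for the top-k signature uses |standardized U| as
the discriminatory-power statistic, ties broken by |log2 FC| then gene id;
log2 FC uses pseudocount 1 on group means so zero-mean genes stay finite.
Mitochondrial/ribosomal exclusion is left to an upstream gene list since
identifier conventions vary across references.

## Module score

Score = mean log-expression of signature genes − mean of expression-matched
controls: genes are ranked by average expression, cut into `n_bins` (24)
equal-size bins, and `n_ctrl` (100) controls per signature gene are drawn
seeded, without replacement, from the gene's bin (the pooled control set is
deduplicated). Defaults follow the widely used single-cell scoring
convention. Subtracting bin-matched controls cancels any additive shift of
the matrix — an invariant under test. A `--no-control` mode returns the
plain signature mean.

## Elastic-net stability selection

**Solver.** Penalized logistic regression,
`-(1/n)·loglik + λ(α‖β‖₁ + (1-α)/2‖β‖₂²)`, intercept unpenalized,
features standardized to mean 0 / population sd 1 on the data entering each
fit (constant features dropped); coefficients stay on the standardized
scale, which keeps response scores and the −0.01 threshold on a stable
scale across cohorts. The solver is IRLS with cyclic coordinate descent on
the weighted least-squares approximation, warm-started along a descending
λ path with active-set cycling, probabilities clamped to [1e-5, 1−1e-5],
and convergence at max coefficient change < 1e-7. The ℓ1 threshold is
inflated by one part in 1e12 so the analytic `lambda_max` boundary
(|gradient| = λα at machine precision) resolves to an exactly zero
coefficient vector. The solver is verified in the test suite against
scikit-learn's saga solver (atol 2e-6), against R glmnet on a shared path
(atol 1e-4), and against a dense brute-force grid on a tiny problem.

**λ selection.** The path has `n_lambda` (100) points, log-spaced from the
closed-form `lambda_max = max_g |⟨x_g, y−ȳ⟩|/(n·α)` (α = 0 uses the
conventional α = 0.001 surrogate) down to `1e-4·lambda_max`. λ_min is the
path point minimizing the mean held-out binomial deviance over stratified
5-fold cross-validation, each fold re-standardized on its own training
part. The mean deviance-vs-λ curve per α is emitted as a diagnostic.

**Resampling design.** `n_partitions` (200) stratified 70/30 splits,
partition i seeded with `master_seed + i`. Stratification is a deliberate
strengthening of plain random splitting — it prevents single-class training
sets in small cohorts — and can be disabled (`stratify=False`) for the
literal protocol. Within each partition and each α on the 0–1 grid
(step 0.1), `n_bootstrap` (100) resamples with replacement to the original
training size (single-class resamples redrawn, ≤ 50 attempts, so counts
stay out of a common denominator) are refit at the fixed (α, λ_min); genes
with non-zero coefficients count as selected. The top-33 genes by selection
frequency (boundary ties by larger mean |coefficient|, then gene id) form
the scenario's stable set.

**Overlap and weights.** Default `strict` mode intersects the stable sets
over every (partition, α > 0) scenario; the pure-ridge α = 0 is computed
for the deviance diagnostics but excluded from selection because it never
produces a sparse set. Because the protocol's wording is ambiguous about
whether the intersection runs over partitions as well as α, a `fraction`
mode is also provided: a gene qualifies when it is in the stable set for
every α in ≥ q (default 0.5) of partitions. The predictive signature's
weight per gene is the median of all its pooled non-zero coefficients
across bootstraps, α values (> 0), and partitions; an even count averages
the central pair.

## Response score and validation

Score_j = Σ_g w_g · z_gj over signature genes present in the matrix
(absent genes dropped with a logged warning), where z is per-gene
standardized log expression. Responders are the ROC positive class;
classification is `score > threshold` (strict), so the −0.01 default makes
"non-negative" responder-leaning. AUC uses the midrank (Mann-Whitney)
formulation; Youden's J is maximized over all midpoints between distinct
scores plus ±∞, ties resolved toward higher sensitivity then lower
threshold. Validation draws 1,000 subsets of 20 samples without
replacement (single-class subsets redrawn, seeded — required for ROC
computability), pooling studies freely, and reports full AUC /
sensitivity / specificity / threshold distributions; the fixed-threshold
confusion is reported per study and pooled.

## Synthetic cohort generator

Counts are NB with variance μ + φμ² (φ = 0.2 default):
`mean = s_j · b_{batch(j),g} · μ_g · 2^(δ_g z_j)` with log-normal library
sizes (sd 0.3), per-(gene, batch) log2-normal batch shifts (sd 0.2; the
new-onset study gets two baseline batches so the batch stage has work to
do), gene baselines `log μ_g ~ N(4, 1.5²)`, and `z_j = ±1/2` for treated
R/NR. Planted genes carry `|δ_g|` = `effect_log2fc` with sign by planted
direction. Placebo/control samples draw a continuous latent progression
score `z_j ~ U(-1/2, 1/2)`; placebo-arm expression shifts act only on the
placebo-progression gene set, which overlaps the planted set by
`overlap_fraction` (0.5) so the exclusion filter has true and false
targets. Outcomes are linear in the latent score, truncated at 0:
C-peptide %baseline ≈ 70 + 60·z + N(0, 15²) (responders ≈ 100%,
nonresponders ≈ 40%), months-to-diagnosis ≈ 24 + 24·z + N(0, 6²); the
month-12 C-peptide outcome adds correlated noise to month 6. Untreated
controls keep C-peptide outcomes missing. Default cohort sizes mirror the
two emulated trials (30 + 15 and 42 + 31 samples).

The generator plants *independent* signal genes with multiplicative
effects and linear outcome coupling; it does not emulate gene-gene
correlation blocks, cell-type composition shifts, outcome nonlinearity, or
count over-dispersion heterogeneity. Passing recovery tests therefore show
the machinery is correct and calibrated under its own assumptions — not
that the clinical effect sizes are attainable on real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced budgets chosen as the smallest
configurations that still exercise every code path: 20 partitions × 2–5 α ×
25 bootstraps on 200-gene, 60–80-sample cohorts, with a 30-point λ path.
The full protocol scale (200 × 11 × 100, 100-point path) is the library
default. Ties anywhere (ranking, Youden, top-k) are broken
deterministically as described so identical configuration + master seed
reproduce outputs bit for bit; every stage seed derives from the master
seed by hashing the stage name, so stages can be re-run in isolation.

## Known limitations

- `median-center` aligns only batch locations; variance and count-model
  batch effects need the `external` hook.
- Strict overlap becomes extremely conservative as partitions grow; with
  weak signal it can return an empty panel (the pure-noise null test
  relies on exactly this behavior). The fraction mode is the pragmatic
  relaxation.
- The exact Wilcoxon branch is limited to ≤ 8 per group without ties;
  beyond that the tie/continuity-corrected normal approximation is used.
- Scores are standardized within the scored cohort, so single-sample
  scoring requires externally supplied gene means/sds.
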