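# stabsig

Bootstrap-stabilized elastic-net gene signatures and response scores for
anti-CD3 (teplizumab) therapy transcriptomics.

## The problem

Teplizumab delays progression of autoimmune type 1 diabetes, but responses
are heterogeneous and there are no validated molecular markers to tell
likely responders (R) from nonresponders (NR) before treatment. Given bulk
whole-blood RNA-seq count matrices from treated cohorts together with
clinical outcomes — C-peptide AUC as a percentage of baseline, or months to
clinical diagnosis — this package:

1. **derives R/NR gene signatures** by per-gene Pearson correlation of
   expression against the continuous outcome (with optional exclusion of
   genes that also track progression in a placebo arm, and cross-study
   intersection), or by two-group Wilcoxon rank-sum differential expression
   with Bonferroni correction and top-k ranking;
2. **selects a stable predictive gene panel** with elastic-net logistic
   regression under repeated data partitioning and bootstrap resampling;
3. **computes a per-sample response score** and validates it by repeated
   subsampled ROC analysis with Youden-optimal operating points and a fixed
   decision threshold.

Because the trial data are access-controlled, a first-class synthetic
cohort generator reproduces their statistical structure (two studies,
treated/placebo/control arms, negative-binomial counts with library-size
and batch effects, outcomes linearly coupled to a planted signal) so every
stage can be tested against a known ground truth.

## The model

Counts are normalized with median-of-ratios size factors
`s_j = median_g counts[g,j] / (prod_k counts[g,k])^(1/m)` and filtered to
genes with ≥ 10 reads in ≥ 40% of samples. On `X` = log2(normalized + 1)
expression of the labeled treated samples, the selection stage minimizes
the penalized binomial deviance

    -(1/n) Σ_i [y_i log p_i + (1-y_i) log(1-p_i)]
        + λ (α‖β‖₁ + (1-α)/2 ‖β‖₂²)

over a descending λ path (features standardized per fit, intercept
unpenalized), choosing λ_min by 5-fold cross-validated deviance for each α.
For every (partition, α) scenario, 100 bootstrap refits at the fixed
(α, λ_min) yield per-gene selection frequencies; the top-33 genes per
scenario form its stable set, the stable sets are intersected across all
α > 0 and partitions, and each surviving gene's weight is the median of its
pooled non-zero coefficients. The response score of sample j is then
`Σ_g w_g · z_gj` over signature genes g with z-scored expression, and
validation reports the distribution of ROC AUC / sensitivity / specificity
over 1,000 random 20-sample subsets plus FP/FN rates at a fixed threshold
of −0.01 (responder ⇔ score > threshold).

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
cohort (the bulky intermediate matrices they exchange are regenerated on the
fly and are not committed; small result tables live under `results/`):

```bash
python analysis/01_simulate_cohorts.py     # 2,000 genes x 118 samples, planted 50+50
python analysis/02_preprocess.py           # batch-center, filter, size factors
python analysis/03_derive_signatures.py    # correlation signatures per study
python analysis/04_stability_selection.py  # elastic-net stability selection
python analysis/05_validate_response_score.py
```

On the default configuration (seed 2026) this prints, among other things:

```
kept 1768/2000 genes; size factors span 0.478-1.942

                  signature  positive  negative
                   A_month6        72        81
                 A_baseline        33        41
B_baseline_placebo_excluded        83        71
          combined_baseline        26        28
combined positive signature: 26 genes, 26 of 50 planted
module score R vs NR: mean 0.524 vs -0.489, one-sided rank-sum p = 1.52e-13

selection finished in 220s; predictive signature has 3 genes
vs ground truth: recall 0.03, precision 1.00

1,000 x 20-sample ROC: mean AUC 0.999, mean sensitivity 99.7%, mean specificity 99.7%
```

Reading: the per-study correlation signatures capture tens of genes each
and their cross-study intersection is almost pure planted signal (26/26
correct). The strict across-all-scenarios intersection in the selection
stage is deliberately conservative — at this cohort size and a modest
planted effect it keeps only 3 genes, every one correct (precision 1.0),
and even that small panel separates responders essentially perfectly
(mean subsampled AUC 0.999; one nonresponder above the −0.01 threshold).
`stabsig.StabilityConfig(overlap_mode="fraction")` relaxes the
intersection when a larger panel is wanted.

The same stages are available as a CLI
(`stabsig simulate|preprocess|derive-signature|score-signature|stability-select|validate|run-all`)
for use on real count matrices; see `stabsig --help`.

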