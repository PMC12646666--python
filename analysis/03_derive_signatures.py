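"""Derive correlation-based responder/nonresponder signatures per study.

Mirrors the clinical signature workflow on the simulated cohort:

* study A (new-onset), month-6 outcome: genes correlated with C-peptide AUC
  %baseline at P < 0.05 -> R / NR signatures;
* study A baseline: correlation with the month-12 C-peptide outcome at
  P < 0.01;
* study B (prevention), baseline: correlation with time to diagnosis at
  P < 0.05, excluding genes that also track progression in the placebo arm;
* combined baseline signatures: the cross-study intersections.

Also scores every sample for the combined positive signature against
expression-matched controls and compares responder vs nonresponder scores.
Writes signature TSVs and a summary to results/signatures/.
"""

from pathlib import Path

import pandas as pd
import scipy.stats

from stabsig import (NormalizedMatrix, align_counts_metadata, combine_signatures,
                     exclude_placebo_correlated, log2_normalized, pearson_signature,
                     read_count_matrix, read_metadata, signature_score,
                     write_signature)

ROOT = Path(__file__).resolve().parents[1] / "results"


def _subset(expr, sample_ids):
    pos = {s: i for i, s in enumerate(expr.sample_ids)}
    cols = [pos[s] for s in sample_ids]
    return NormalizedMatrix(list(expr.gene_ids), list(sample_ids),
                            expr.values[:, cols])


def main() -> None:
    cm = read_count_matrix(ROOT / "preprocess" / "counts_filtered.tsv")
    meta = align_counts_metadata(cm, read_metadata(ROOT / "data" / "metadata.tsv"))
    truth = pd.read_csv(ROOT / "data" / "ground_truth.tsv", sep="\t")
    planted_pos = set(truth.loc[truth["role"] == "planted_pos", "gene_id"])
    expr = log2_normalized(cm)
    out = ROOT / "signatures"
    out.mkdir(parents=True, exist_ok=True)

    by = meta.set_index("sample_id")
    a_treated = meta[(meta["study"] == "AbATE") & (meta["arm"] == "treated")]
    b_treated = meta[(meta["study"] == "TN10") & (meta["arm"] == "treated")]
    b_placebo = meta[(meta["study"] == "TN10") & (meta["arm"] == "placebo")]

    # study A, month 6, P < 0.05
    ea = _subset(expr, list(a_treated["sample_id"]))
    ya6 = by.loc[ea.sample_ids, "cpep_auc_pct_baseline_m6"]
    a_m6_pos, a_m6_neg = pearson_signature(ea, ya6, 0.05, name_prefix="A_month6")

    # study A, baseline expression vs month-12 outcome, P < 0.01
    ya12 = by.loc[ea.sample_ids, "cpep_auc_pct_baseline_m12"]
    a_bl_pos, a_bl_neg = pearson_signature(ea, ya12, 0.01, name_prefix="A_baseline")

    # study B, baseline vs time to diagnosis, P < 0.05, placebo-excluded
    eb = _subset(expr, list(b_treated["sample_id"]))
    yb = by.loc[eb.sample_ids, "time_to_diagnosis"]
    b_pos, b_neg = pearson_signature(eb, yb, 0.05, name_prefix="B_baseline")
    ep = _subset(expr, list(b_placebo["sample_id"]))
    yp = by.loc[ep.sample_ids, "time_to_diagnosis"]
    n_before = (len(b_pos), len(b_neg))
    b_pos = exclude_placebo_correlated(b_pos, ep, yp, 0.05)
    b_neg = exclude_placebo_correlated(b_neg, ep, yp, 0.05)

    combined_pos = combine_signatures(a_bl_pos, b_pos, name="combined_baseline_pos")
    combined_neg = combine_signatures(a_bl_neg, b_neg, name="combined_baseline_neg")

    for sig in (a_m6_pos, a_m6_neg, a_bl_pos, a_bl_neg, b_pos, b_neg,
                combined_pos, combined_neg):
        write_signature(sig, out / f"{sig.name}.tsv")

    # module score of the combined positive signature, R vs NR (all treated)
    scores = signature_score(expr, combined_pos, seed=7)
    merged = scores.merge(meta, left_on="unit_id", right_on="sample_id")
    r = merged.loc[merged["response"] == "R", "score"]
    nr = merged.loc[merged["response"] == "NR", "score"]
    mwu = scipy.stats.mannwhitneyu(r, nr, alternative="greater")
    scores.to_csv(out / "combined_pos_module_scores.tsv", sep="\t", index=False)

    summary = pd.DataFrame([
        {"signature": "A_month6", "positive": len(a_m6_pos), "negative": len(a_m6_neg)},
        {"signature": "A_baseline", "positive": len(a_bl_pos),
         "negative": len(a_bl_neg)},
        {"signature": "B_baseline_placebo_excluded", "positive": len(b_pos),
         "negative": len(b_neg)},
        {"signature": "combined_baseline", "positive": len(combined_pos),
         "negative": len(combined_neg)},
    ])
    summary.to_csv(out / "signature_sizes.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"placebo exclusion removed {n_before[0] - len(b_pos)} positive and "
          f"{n_before[1] - len(b_neg)} negative genes")
    hits = len(set(combined_pos.gene_ids) & planted_pos)
    print(f"combined positive signature: {len(combined_pos)} genes, "
          f"{hits} of {len(planted_pos)} planted")
    print(f"module score R vs NR: mean {r.mean():.3f} vs {nr.mean():.3f}, "
          f"one-sided rank-sum p = {mwu.pvalue:.2e}")


if __name__ == "__main__":
    main()
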