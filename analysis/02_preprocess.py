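"""Preprocess the simulated cohort: batch integration, filtering, normalization.

Median-centers the two baseline batches of the AbATE-like study (standing in
for an empirical-Bayes batch adjuster), keeps genes with >= 10 reads in
>= 40% of samples, and computes median-of-ratios size factors. Writes the
filtered counts, size factors, and a preprocessing report to
results/preprocess/.
"""

from pathlib import Path

import pandas as pd

from stabsig import (align_counts_metadata, batch_adjust, filter_genes,
                     read_count_matrix, read_metadata, size_factors,
                     write_count_matrix)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cm = read_count_matrix(ROOT / "data" / "counts.tsv")
    meta = align_counts_metadata(cm, read_metadata(ROOT / "data" / "metadata.tsv"))
    out = ROOT / "preprocess"
    out.mkdir(parents=True, exist_ok=True)

    cm_adj = batch_adjust(cm, meta["batch"], method="median-center")
    cm_filt, report = filter_genes(cm_adj, min_count=10, min_sample_frac=0.40)
    sf = size_factors(cm_filt)
    sf_raw = size_factors(cm_filt, rescale=False)

    write_count_matrix(cm_filt, out / "counts_filtered.tsv")
    pd.DataFrame({"sample_id": cm_filt.sample_ids, "size_factor": sf,
                  "size_factor_unrescaled": sf_raw}).to_csv(
        out / "size_factors.tsv", sep="\t", index=False)
    pd.DataFrame([{"n_genes_in": report.n_genes_in,
                   "n_genes_kept": report.n_genes_kept,
                   "batch_method": "median-center", **report.thresholds}]).to_csv(
        out / "preprocess_report.tsv", sep="\t", index=False)
    print(f"kept {report.n_genes_kept}/{report.n_genes_in} genes; "
          f"size factors span {sf.min():.3f}-{sf.max():.3f}")


if __name__ == "__main__":
    main()
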