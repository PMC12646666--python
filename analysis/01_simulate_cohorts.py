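"""Simulate the two-study benchmark cohort used by the downstream analyses.

Emulates the structure of two anti-CD3 trial cohorts: a new-onset study
("AbATE-like": treated responders/nonresponders plus untreated controls,
two baseline batches) and a prevention study ("TN10-like": treated plus
placebo arm), with negative-binomial counts, library-size and batch
effects, and clinical outcomes coupled to a planted 50-gene responder and
50-gene nonresponder signal.

Writes counts, metadata, ground truth, and the resolved configuration to
results/data/.
"""

from pathlib import Path

import yaml

from stabsig import SimulationConfig, simulate_cohort, write_count_matrix, write_metadata

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2026

CONFIG = SimulationConfig(seed=SEED)  # package defaults ARE the study conditions


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cm, meta, truth = simulate_cohort(CONFIG)
    write_count_matrix(cm, OUT / "counts.tsv")
    write_metadata(meta, OUT / "metadata.tsv")
    truth.to_frame().to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
    (OUT / "config.yaml").write_text(yaml.safe_dump(CONFIG.to_dict()))
    n_by = meta.groupby(["study", "arm", "response"]).size()
    print(f"simulated {cm.n_genes} genes x {cm.n_samples} samples")
    print(n_by.to_string())
    print(f"planted: {len(truth.planted_pos)} positive, {len(truth.planted_neg)} "
          f"negative, {len(truth.placebo_progression_genes)} placebo-progression")


if __name__ == "__main__":
    main()
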