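"""End-to-end orchestration: simulate/load -> preprocess -> select -> validate.

A run is driven by a :class:`PipelineConfig`, derives every stage seed
deterministically from one master seed, and records a :class:`RunManifest`
with resolved configuration, per-stage wall time and SHA-256 digests of all
written artifacts, so identical (config, seed, inputs) reproduce identical
outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (align_counts_metadata, read_count_matrix, read_metadata,
                 write_count_matrix, write_metadata)
from .preprocess import batch_adjust, filter_genes, log2_normalized, size_factors
from .simulate import SimulationConfig, simulate_cohort
from .stability import StabilityConfig, run_stability_pipeline
from .validation import (classify_fixed_threshold, resampled_validation,
                         response_score, standardize_expression)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_full", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed hashed with the stage name.

    Kept below 2**31 so every consumer (numpy, sklearn) accepts it.
    """
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results/run"
    counts_path: str | Path | None = None      # None -> simulate
    metadata_path: str | Path | None = None
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    min_count: int = 10
    min_sample_frac: float = 0.40
    batch_method: str = "median-center"
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    n_validation_iterations: int = 1000
    validation_subset_size: int = 20
    fixed_threshold: float = -0.01
    master_seed: int = 0

    def validate(self) -> None:
        for p in (self.counts_path, self.metadata_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.counts_path is None) != (self.metadata_path is None):
            raise ValueError("counts_path and metadata_path must be given together")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    digests: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "wall_time_s": round(seconds, 3), **info})

    def digest_file(self, path: str | Path) -> None:
        path = Path(path)
        self.digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages,
             "digests": self.digests, "warnings": self.warnings},
            indent=2, default=str) + "\n")


def run_full(config: PipelineConfig) -> RunManifest:
    """Execute the whole pipeline and write all artifacts under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "master_seed": config.master_seed,
            "min_count": config.min_count,
            "min_sample_frac": config.min_sample_frac,
            "batch_method": config.batch_method,
            "stability": config.stability.__dict__
            | {"alpha_grid": list(config.stability.alpha_grid)},
            "n_validation_iterations": config.n_validation_iterations,
            "validation_subset_size": config.validation_subset_size,
            "fixed_threshold": config.fixed_threshold,
            "simulated": config.counts_path is None,
        },
        version=__version__,
    )

    # --- input stage: load or simulate -----------------------------------
    t0 = time.perf_counter()
    if config.counts_path is not None:
        cm = read_count_matrix(config.counts_path)
        meta = read_metadata(config.metadata_path)
    else:
        sim_cfg = SimulationConfig.from_dict(
            config.sim_config.to_dict() | {"seed": stage_seed(config.master_seed,
                                                              "simulate")})
        cm, meta, truth = simulate_cohort(sim_cfg)
        truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        manifest.digest_file(out / "ground_truth.tsv")
        write_count_matrix(cm, out / "counts.tsv")
        write_metadata(meta, out / "metadata.tsv")
        manifest.digest_file(out / "counts.tsv")
        manifest.digest_file(out / "metadata.tsv")
    meta = align_counts_metadata(cm, meta)
    manifest.add_stage("input", time.perf_counter() - t0,
                       n_genes=cm.n_genes, n_samples=cm.n_samples)

    # --- preprocess: batch-adjust, filter, normalize ----------------------
    t0 = time.perf_counter()
    cm_adj = batch_adjust(cm, meta["batch"], method=config.batch_method)
    cm_filt, report = filter_genes(cm_adj, config.min_count, config.min_sample_frac)
    sf = size_factors(cm_filt)
    expr = log2_normalized(cm_filt, sf)
    pd.DataFrame({"sample_id": cm_filt.sample_ids, "size_factor": sf}).to_csv(
        out / "size_factors.tsv", sep="\t", index=False)
    manifest.digest_file(out / "size_factors.tsv")
    manifest.add_stage("preprocess", time.perf_counter() - t0,
                       batch_method=config.batch_method,
                       n_genes_in=report.n_genes_in, n_genes_kept=report.n_genes_kept,
                       thresholds=report.thresholds)

    # --- stability selection on treated, labeled samples ------------------
    t0 = time.perf_counter()
    labeled = meta[(meta["arm"] == "treated") & meta["response"].isin(["R", "NR"])]
    sample_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    cols = [sample_pos[s] for s in labeled["sample_id"]]
    X = expr.values[:, cols].T
    y = (labeled["response"] == "R").to_numpy(dtype=float)
    stab_cfg = StabilityConfig(**{
        **config.stability.__dict__,
        "master_seed": stage_seed(config.master_seed, "stability")})
    freq, signature, diagnostics = run_stability_pipeline(X, y, expr.gene_ids, stab_cfg)
    freq.counts.to_csv(out / "selection_frequencies.tsv", sep="\t", index=False)
    signature.entries.to_csv(out / "predictive_signature.tsv", sep="\t", index=False)
    diagnostics["cv_curves"].to_csv(out / "cv_deviance_curves.tsv", sep="\t",
                                    index=False)
    for name in ("selection_frequencies.tsv", "predictive_signature.tsv",
                 "cv_deviance_curves.tsv"):
        manifest.digest_file(out / name)
    manifest.add_stage("stability_selection", time.perf_counter() - t0,
                       n_signature_genes=len(signature),
                       n_scenarios=len(diagnostics["stable_sets"]))

    # --- response score + validation --------------------------------------
    t0 = time.perf_counter()
    if len(signature) == 0:
        manifest.warnings.append("empty predictive signature; validation skipped")
        manifest.write(out / "manifest.json")
        return manifest
    z = standardize_expression(expr)
    scores = response_score(z, signature, meta)
    scores.to_csv(out / "response_scores.tsv", sep="\t", index=False)
    manifest.digest_file(out / "response_scores.tsv")
    labeled_scores = scores[scores["response"].isin(["R", "NR"])]
    summary = resampled_validation(
        labeled_scores, n_iterations=config.n_validation_iterations,
        subset_size=min(config.validation_subset_size, len(labeled_scores)),
        seed=stage_seed(config.master_seed, "validation"))
    summary.to_frame().to_csv(out / "validation_iterations.tsv", sep="\t", index=False)
    confusion = classify_fixed_threshold(scores, threshold=config.fixed_threshold)
    confusion.to_csv(out / "fixed_threshold_confusion.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "mean_auc": summary.mean_auc, "mean_sensitivity": summary.mean_sensitivity,
        "mean_specificity": summary.mean_specificity,
        "n_iterations": config.n_validation_iterations,
        "subset_size": config.validation_subset_size,
        "fixed_threshold": config.fixed_threshold,
    }]).to_csv(out / "validation_summary.tsv", sep="\t", index=False)
    for name in ("validation_iterations.tsv", "fixed_threshold_confusion.tsv",
                 "validation_summary.tsv"):
        manifest.digest_file(out / name)
    manifest.add_stage("validation", time.perf_counter() - t0,
                       mean_auc=summary.mean_auc,
                       mean_sensitivity=summary.mean_sensitivity,
                       mean_specificity=summary.mean_specificity)

    manifest.write(out / "manifest.json")
    return manifest
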