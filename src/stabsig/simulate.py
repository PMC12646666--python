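"""Synthetic two-study cohort generator with a planted responder signal.

Emulates the statistical structure of two bulk whole-blood RNA-seq trial
cohorts (a new-onset study with treated and untreated-control arms, and a
prevention study with treated and placebo arms): negative-binomial counts
with per-sample library sizes and per-(gene, batch) multiplicative batch
effects, binary responder status in treated arms, and continuous clinical
outcomes (C-peptide AUC as % of baseline; months to diagnosis) linearly
coupled to a latent response score. A configurable subset of genes tracks
disease progression in the placebo arm so the placebo-exclusion filter has
signal to remove.

Counts follow NB(mean mu, variance mu + phi * mu^2). On planted signature
genes the mean is shifted by ``2^(delta_g * z_j)`` where ``z_j`` is +1/2 for
responders and -1/2 for nonresponders and ``|delta_g| = effect_log2fc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["StudyDesign", "SimulationConfig", "GroundTruth", "simulate_cohort",
           "truth_overlap", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class StudyDesign:
    """Per-study sample sizes by arm and responder status."""

    n_treated_R: int
    n_treated_NR: int
    n_placebo: int = 0
    n_control: int = 0
    n_batches: int = 1

    @property
    def n_samples(self) -> int:
        return self.n_treated_R + self.n_treated_NR + self.n_placebo + self.n_control


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_signal_pos: int = 50
    n_signal_neg: int = 50
    studies: Mapping[str, StudyDesign] = field(default_factory=lambda: {
        # sizes mirror the two trial cohorts the generator emulates:
        # new-onset arm R/NR/untreated controls and prevention arm with placebo
        "AbATE": StudyDesign(n_treated_R=14, n_treated_NR=16, n_control=15, n_batches=2),
        "TN10": StudyDesign(n_treated_R=22, n_treated_NR=20, n_placebo=31),
    })
    baseline_log_mean: float = 4.0      # mean of log gene mean (natural log)
    baseline_log_sd: float = 1.5        # sd of log gene mean
    dispersion: float = 0.2             # NB phi, variance = mu + phi mu^2
    library_size_log_sd: float = 0.3    # sd of log-normal library size factor
    batch_log_fc_sd: float = 0.2        # sd of per-(gene,batch) log2 shifts
    effect_log2fc: float = 1.0          # |log2 FC| planted between R and NR
    outcome_noise_sd: float = 15.0      # sd of C-peptide outcome noise (% points)
    placebo_progression_genes: int = 40
    overlap_fraction: float = 0.5       # fraction of placebo genes inside planted set
    # outcome linear models: outcome = intercept + slope * latent + noise, >= 0
    cpep_intercept: float = 70.0
    cpep_slope: float = 60.0
    ttd_intercept: float = 24.0         # months
    ttd_slope: float = 24.0
    ttd_noise_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_signal_pos + self.n_signal_neg > self.n_genes:
            raise ValueError("planted signal genes exceed n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("library_size_log_sd", "batch_log_fc_sd", "outcome_noise_sd",
                     "ttd_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.placebo_progression_genes > self.n_genes:
            raise ValueError("placebo_progression_genes exceeds n_genes")
        for study, d in self.studies.items():
            if d.n_treated_R < 1 or d.n_treated_NR < 1:
                raise ValueError(f"study {study!r} needs >= 1 treated R and NR sample")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["studies"] = {k: asdict(v) for k, v in dict(self.studies).items()}
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "studies" in d:
            d["studies"] = {k: StudyDesign(**v) if not isinstance(v, StudyDesign) else v
                            for k, v in dict(d["studies"]).items()}
        return SimulationConfig(**d)


DEFAULT_CONFIG = SimulationConfig()


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery scoring."""

    planted_pos: set[str]
    planted_neg: set[str]
    placebo_progression_genes: set[str]
    latent_score: pd.Series  # per-sample latent response/progression score

    def __post_init__(self) -> None:
        if self.planted_pos & self.planted_neg:
            raise ValueError("planted positive and negative sets must be disjoint")

    @property
    def planted(self) -> set[str]:
        return self.planted_pos | self.planted_neg

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "planted_pos") for g in sorted(self.planted_pos)]
        rows += [(g, "planted_neg") for g in sorted(self.planted_neg)]
        rows += [(g, "placebo_progression") for g in sorted(self.placebo_progression_genes)]
        return pd.DataFrame(rows, columns=["gene_id", "role"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + phi mu^2: shape r = 1/phi, p = r / (r + mu)."""
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_cohort(config: SimulationConfig = DEFAULT_CONFIG,
                    ) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw one two-study cohort: counts, metadata, and ground truth.

    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    gene_ids = [f"gene{i:05d}" for i in range(G)]
    mu = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=G))

    pos_idx = np.arange(config.n_signal_pos)
    neg_idx = np.arange(config.n_signal_pos, config.n_signal_pos + config.n_signal_neg)
    delta = np.zeros(G)
    delta[pos_idx] = config.effect_log2fc
    delta[neg_idx] = -config.effect_log2fc

    # placebo progression genes: overlap_fraction drawn from the planted set,
    # the rest from non-planted genes
    n_pp = config.placebo_progression_genes
    n_from_planted = int(round(config.overlap_fraction * n_pp))
    planted_idx = np.concatenate([pos_idx, neg_idx])
    n_from_planted = min(n_from_planted, len(planted_idx))
    other_idx = np.setdiff1d(np.arange(G), planted_idx)
    pp_idx = np.concatenate([
        rng.choice(planted_idx, size=n_from_planted, replace=False),
        rng.choice(other_idx, size=min(n_pp - n_from_planted, len(other_idx)),
                   replace=False),
    ]).astype(int)
    pp_delta = np.zeros(G)
    # progression-linked shift direction mirrors planted sign where overlapping,
    # otherwise random sign
    pp_delta[pp_idx] = np.where(
        delta[pp_idx] != 0, np.sign(delta[pp_idx]), rng.choice([-1.0, 1.0], size=len(pp_idx))
    ) * config.effect_log2fc

    sample_rows = []
    latent = []
    for study, design in dict(config.studies).items():
        groups = (
            [("treated", "R")] * design.n_treated_R
            + [("treated", "NR")] * design.n_treated_NR
            + [("placebo", "unknown")] * design.n_placebo
            + [("control", "unknown")] * design.n_control
        )
        for k, (arm, resp) in enumerate(groups):
            sid = f"{study}_s{k:03d}"
            batch = f"{study}_b{k % design.n_batches}"
            if arm == "treated":
                z = 0.5 if resp == "R" else -0.5
            else:
                # placebo/control progression latent on the same +-1/2 scale
                z = rng.uniform(-0.5, 0.5)
            sample_rows.append((sid, study, arm, resp, batch))
            latent.append(z)
    meta = pd.DataFrame(sample_rows, columns=["sample_id", "study", "arm", "response", "batch"])
    z = np.asarray(latent)
    n = len(meta)

    # per-(gene, batch) multiplicative batch shifts, log2-normal
    batches = sorted(meta["batch"].unique())
    batch_fc = {b: 2.0 ** rng.normal(0.0, config.batch_log_fc_sd, size=G) for b in batches}
    s_lib = np.exp(rng.normal(0.0, config.library_size_log_sd, size=n))

    treated = (meta["arm"] == "treated").to_numpy()
    placebo = (meta["arm"] == "placebo").to_numpy()
    counts = np.empty((G, n), dtype=np.int64)
    for j in range(n):
        eff = delta * z[j] if treated[j] else (pp_delta * z[j] if placebo[j] else 0.0)
        mean_j = s_lib[j] * batch_fc[meta["batch"].iloc[j]] * mu * 2.0 ** eff
        counts[:, j] = _nb_draw(rng, mean_j, config.dispersion)

    # outcomes: linear in the latent score, truncated at zero; controls keep
    # the C-peptide outcome missing (they received no therapy to respond to)
    noise = rng.normal(0.0, config.outcome_noise_sd, size=n)
    cpep = np.maximum(0.0, config.cpep_intercept + config.cpep_slope * z + noise)
    ttd_noise = rng.normal(0.0, config.ttd_noise_sd, size=n)
    ttd = np.maximum(0.0, config.ttd_intercept + config.ttd_slope * z + ttd_noise)
    meta["cpep_auc_pct_baseline_m6"] = np.where(treated | placebo, cpep, np.nan)
    meta["cpep_auc_pct_baseline_m12"] = np.where(
        treated | placebo,
        np.maximum(0.0, cpep + rng.normal(0.0, config.outcome_noise_sd / 2, size=n)
                   - 5.0),
        np.nan,
    )
    meta["time_to_diagnosis"] = ttd
    meta["age"] = np.round(rng.uniform(8.0, 35.0, size=n), 1)
    meta["sex"] = rng.choice(["F", "M"], size=n)

    cm = CountMatrix(gene_ids, list(meta["sample_id"]), counts)
    truth = GroundTruth(
        planted_pos={gene_ids[i] for i in pos_idx},
        planted_neg={gene_ids[i] for i in neg_idx},
        placebo_progression_genes={gene_ids[i] for i in pp_idx},
        latent_score=pd.Series(z, index=meta["sample_id"].to_numpy(), name="latent_score"),
    )
    return cm, meta, truth


def truth_overlap(selected: set[str], truth: GroundTruth) -> tuple[float, float]:
    """Recall and precision of a selected gene set against the planted set.

    Precision of an empty selection is 1.0 by convention (nothing wrongly
    selected); a warning-level flag is left to the caller via the value.
    """
    selected = set(selected)
    planted = truth.planted
    hit = len(selected & planted)
    recall = hit / len(planted) if planted else 1.0
    precision = hit / len(selected) if selected else 1.0
    return recall, precision
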