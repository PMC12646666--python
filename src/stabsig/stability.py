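"""Bootstrap-stabilized elastic-net feature selection.

The pipeline repeatedly (1) partitions the cohort into stratified 70/30
train/test splits, (2) for each penalty-mixing value α picks the
regularization strength λ by stratified cross-validation on the training
split (minimum mean held-out binomial deviance), (3) refits on bootstrap
resamples of the training split at the fixed (α, λ) and counts how often
each gene receives a non-zero coefficient, (4) keeps the top-k most
frequently selected genes per (partition, α) scenario, (5) intersects those
stable sets across scenarios (α = 0 excluded — ridge never produces a
sparse set), and (6) assigns each surviving gene the median of all its
pooled non-zero coefficients as its weight in the predictive signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enet import fit_enet, fit_enet_cv
from .io import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["StabilityConfig", "SelectionFrequencyTable", "PredictiveSignature",
           "make_partitions", "bootstrap_select", "top_frequency_features",
           "overlap_features", "median_coefficients", "run_stability_pipeline"]


def _default_alpha_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass(frozen=True)
class StabilityConfig:
    n_partitions: int = 200
    train_frac: float = 0.70
    alpha_grid: tuple[float, ...] = field(default_factory=_default_alpha_grid)
    n_folds: int = 5
    n_bootstrap: int = 100
    top_k: int = 33
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    overlap_mode: str = "strict"        # or "fraction"
    overlap_q: float = 0.5
    stratify: bool = True
    master_seed: int = 0

    @property
    def alphas_for_overlap(self) -> tuple[float, ...]:
        """α values entering the overlap: the grid minus the pure-ridge end."""
        return tuple(a for a in self.alpha_grid if a > 0.0)

    def validate(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ValueError("alpha values must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not self.alphas_for_overlap:
            raise ValueError("alpha grid needs at least one value > 0")
        if self.overlap_mode not in ("strict", "fraction"):
            raise ValueError("overlap_mode must be 'strict' or 'fraction'")


@dataclass
class SelectionFrequencyTable:
    """Per-(partition, α, gene) bootstrap selection counts and pooled coefficients."""

    counts: pd.DataFrame   # columns: partition, alpha, gene_id, count
    coef_values: dict[str, list[float]]  # gene -> all non-zero coefficients seen
    n_bootstrap: int

    def __post_init__(self) -> None:
        if len(self.counts) and self.counts["count"].max() > self.n_bootstrap:
            raise ValidationError("selection count exceeds n_bootstrap")

    def mean_abs_coef(self) -> dict[str, float]:
        return {g: float(np.mean(np.abs(v))) for g, v in self.coef_values.items() if v}


@dataclass
class PredictiveSignature:
    """Stable gene set with median non-zero coefficients as weights."""

    entries: pd.DataFrame  # columns: gene_id, median_coefficient
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) and np.any(self.entries["median_coefficient"] == 0):
            raise ValidationError("predictive signature must not contain zero weights")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])

    def weights(self) -> pd.Series:
        return self.entries.set_index("gene_id")["median_coefficient"]

    def __len__(self) -> int:
        return len(self.entries)


def make_partitions(y: np.ndarray | pd.Series, cfg: StabilityConfig,
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded train/test index splits, stratified by the binary label.

    Partition i uses seed ``master_seed + i``. The training size is
    ``round(train_frac * n)``; with stratification each class contributes
    its proportional share within rounding.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"binary labels required, got classes {list(classes)}")
    if counts.min() < 2:
        raise ValidationError("each class needs >= 2 samples to stratify")
    n = len(y)
    n_train = int(round(cfg.train_frac * n))
    partitions = []
    for i in range(cfg.n_partitions):
        rng = np.random.default_rng(cfg.master_seed + i)
        if cfg.stratify:
            train_idx = []
            # proportional per-class take; largest-remainder rounding to hit n_train
            quota = counts * cfg.train_frac
            take = np.floor(quota).astype(int)
            order = np.argsort(-(quota - take))
            j = 0
            while take.sum() < n_train:
                take[order[j % len(classes)]] += 1
                j += 1
            for cls, t in zip(classes, take):
                members = np.flatnonzero(y == cls)
                train_idx.append(rng.choice(members, size=t, replace=False))
            train = np.sort(np.concatenate(train_idx))
        else:
            train = np.sort(rng.choice(n, size=n_train, replace=False))
        test = np.setdiff1d(np.arange(n), train)
        partitions.append((train, test))
    return partitions


def bootstrap_select(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                     n_bootstrap: int, seed: int, max_redraw: int = 50,
                     ) -> tuple[np.ndarray, list[list[float]]]:
    """Selection counts and coefficient values over bootstrap refits.

    Each iteration resamples the training samples with replacement to the
    original size (redrawing, up to ``max_redraw`` times, if the resample
    holds a single class), fits at the fixed (α, λ), and records which
    features come out non-zero and with what coefficient.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros(p, dtype=int)
    values: list[list[float]] = [[] for _ in range(p)]
    for _ in range(n_bootstrap):
        for _attempt in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise ValidationError("could not draw a two-class bootstrap resample")
        fit = fit_enet(X[idx], y[idx], alpha, lam)
        nz = fit.selected
        counts[nz] += 1
        for j in nz:
            values[j].append(float(fit.coefficients[j]))
    return counts, values


def top_frequency_features(counts: Mapping[str, int] | pd.Series, k: int,
                           mean_abs_coef: Mapping[str, float] | None = None,
                           ) -> list[str]:
    """The k most frequently selected genes (only genes ever selected).

    Boundary ties are broken by larger mean |coefficient|, then gene id.
    Returns fewer than k, with a warning, if fewer genes were ever selected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    mean_abs_coef = mean_abs_coef or {}
    ever = [(g, c) for g, c in counts.items() if c > 0]
    ranked = sorted(ever, key=lambda gc: (-gc[1], -mean_abs_coef.get(gc[0], 0.0), gc[0]))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} gene(s) ever selected; top-{k} truncated")
    return [g for g, _ in ranked[:k]]


def overlap_features(stable_sets: Mapping[tuple[int, float], Sequence[str]],
                     mode: str = "strict", q: float = 0.5) -> set[str]:
    """Genes consistently present across the (partition, α) stable sets.

    ``strict``: intersection over every scenario. ``fraction``: a gene
    qualifies when it sits in the stable set of every α within a partition,
    for at least a fraction ``q`` of partitions.
    """
    if not stable_sets:
        raise ValidationError("no stable sets supplied")
    if mode == "strict":
        out: set[str] | None = None
        for genes in stable_sets.values():
            out = set(genes) if out is None else out & set(genes)
        return out or set()
    if mode == "fraction":
        partitions = sorted({p for p, _ in stable_sets})
        per_partition = []
        for p in partitions:
            inter: set[str] | None = None
            for (pp, _a), genes in stable_sets.items():
                if pp == p:
                    inter = set(genes) if inter is None else inter & set(genes)
            per_partition.append(inter or set())
        threshold = q * len(partitions)
        all_genes = set().union(*per_partition)
        return {g for g in all_genes
                if sum(g in s for s in per_partition) >= threshold}
    raise ValueError("mode must be 'strict' or 'fraction'")


def median_coefficients(freq: SelectionFrequencyTable, overlap: set[str],
                        provenance: dict | None = None) -> PredictiveSignature:
    """Median of each overlap gene's pooled non-zero coefficients."""
    rows = []
    for g in sorted(overlap):
        vals = freq.coef_values.get(g, [])
        if not vals:
            raise ValidationError(f"overlap gene {g!r} was never selected")
        rows.append((g, float(np.median(vals))))
    entries = pd.DataFrame(rows, columns=["gene_id", "median_coefficient"])
    return PredictiveSignature(entries=entries, provenance=provenance or {})


def run_stability_pipeline(X: np.ndarray, y: np.ndarray, gene_ids: Sequence[str],
                           cfg: StabilityConfig,
                           ) -> tuple[SelectionFrequencyTable, PredictiveSignature,
                                      dict]:
    """Full stability-selection run.

    ``X`` is samples x genes (already preprocessed/log-scaled), ``y`` binary
    responder labels (1 = responder). Returns the selection-frequency table,
    the predictive signature, and diagnostics including the mean
    cross-validated deviance-vs-λ curve per α.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gene_ids = list(gene_ids)
    if X.shape[1] != len(gene_ids):
        raise ValidationError("gene_ids length must match X columns")
    partitions = make_partitions(y, cfg)

    count_rows = []
    coef_values: dict[str, list[float]] = {g: [] for g in gene_ids}
    stable_sets: dict[tuple[int, float], list[str]] = {}
    cv_curves = []
    for part_i, (train, _test) in enumerate(partitions):
        Xtr, ytr = X[train], y[train]
        for alpha in cfg.alpha_grid:
            seed = cfg.master_seed + 100_003 * part_i + int(round(alpha * 10))
            fit = fit_enet_cv(Xtr, ytr, alpha, n_folds=cfg.n_folds, seed=seed,
                              n_lambda=cfg.n_lambda,
                              lambda_min_ratio=cfg.lambda_min_ratio)
            cv_curves.append(pd.DataFrame({
                "partition": part_i, "alpha": alpha, "lambda": fit.cv_lambdas,
                "mean_cv_deviance": fit.cv_deviance}))
            if alpha == 0.0:
                # diagnostics only: ridge is in the λ curves but never yields a
                # sparse stable set, so it is excluded from selection entirely
                continue
            counts, values = bootstrap_select(Xtr, ytr, alpha, fit.lam,
                                              cfg.n_bootstrap, seed=seed + 17)
            sel = np.flatnonzero(counts)
            count_map = {gene_ids[j]: int(counts[j]) for j in sel}
            mean_abs = {gene_ids[j]: float(np.mean(np.abs(values[j]))) for j in sel}
            for j in sel:
                count_rows.extend([(part_i, alpha, gene_ids[j], int(counts[j]))])
                coef_values[gene_ids[j]].extend(values[j])
            stable_sets[(part_i, alpha)] = top_frequency_features(
                count_map, cfg.top_k, mean_abs)
        logger.info("partition %d/%d done", part_i + 1, cfg.n_partitions)

    freq = SelectionFrequencyTable(
        counts=pd.DataFrame(count_rows,
                            columns=["partition", "alpha", "gene_id", "count"]),
        coef_values={g: v for g, v in coef_values.items() if v},
        n_bootstrap=cfg.n_bootstrap,
    )
    overlap = overlap_features(stable_sets, mode=cfg.overlap_mode, q=cfg.overlap_q)
    signature = median_coefficients(
        freq, overlap,
        provenance={"config": cfg.__dict__ | {"alpha_grid": list(cfg.alpha_grid)},
                    "n_scenarios": len(stable_sets)})
    diagnostics = {
        "cv_curves": pd.concat(cv_curves, ignore_index=True),
        "stable_sets": stable_sets,
        "overlap": overlap,
        "partitions": partitions,
    }
    return freq, signature, diagnostics
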