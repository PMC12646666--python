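"""Normalization, gene filtering, and pluggable batch adjustment.

The pipeline order mirrors standard bulk RNA-seq practice: batch adjustment
on raw counts, then median-of-ratios size factors, then the expression
filter (a gene is kept when it reaches ``min_count`` reads in at least
``min_sample_frac`` of samples; both thresholds inclusive, the fraction
compared exactly with no rounding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import CountMatrix, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PreprocessReport", "size_factors", "normalize", "filter_genes",
           "batch_adjust", "log2_normalized"]


@dataclass
class PreprocessReport:
    n_genes_in: int
    n_genes_kept: int
    size_factors: np.ndarray | None = None
    batch_method: str = "none"
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes_kept > self.n_genes_in:
            raise ValidationError("kept more genes than were supplied")


def size_factors(cm: CountMatrix, rescale: bool = True) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For each sample j, the factor is the median over genes g (restricted to
    genes with a positive geometric mean, i.e. no zero count in any sample)
    of ``counts[g, j] / geomean_k(counts[g, k])``. With ``rescale=True`` the
    factors are divided by their own geometric mean so they multiply to 1;
    ``rescale=False`` returns the raw medians.
    """
    counts = cm.counts.astype(float)
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        raise ValidationError(
            "no gene has positive counts in every sample; filter all-zero rows "
            "or low-coverage genes before computing size factors"
        )
    used = counts[all_positive]
    geomean = np.exp(np.log(used).mean(axis=1, keepdims=True))
    # the median is taken in ratio space (an even gene count averages the
    # middle pair of ratios, not their logs)
    sf = np.median(used / geomean, axis=0)
    if rescale:
        sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def normalize(cm: CountMatrix, factors: np.ndarray | None = None) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(cm)
    factors = np.asarray(factors, dtype=float)
    return NormalizedMatrix(
        list(cm.gene_ids), list(cm.sample_ids),
        cm.counts / factors[np.newaxis, :], size_factors=factors,
    )


def log2_normalized(cm: CountMatrix, factors: np.ndarray | None = None) -> NormalizedMatrix:
    """log2(normalized count + 1), the expression scale used downstream."""
    nm = normalize(cm, factors)
    return NormalizedMatrix(nm.gene_ids, nm.sample_ids, np.log2(nm.values + 1.0),
                            size_factors=nm.size_factors)


def filter_genes(cm: CountMatrix, min_count: int = 10, min_sample_frac: float = 0.40,
                 ) -> tuple[CountMatrix, PreprocessReport]:
    """Keep genes expressed at >= ``min_count`` in >= ``min_sample_frac`` of samples."""
    if not 0 < min_sample_frac <= 1:
        raise ValueError("min_sample_frac must be in (0, 1]")
    frac = (cm.counts >= min_count).mean(axis=1)
    keep = frac >= min_sample_frac
    kept = cm.subset_genes(keep)
    report = PreprocessReport(
        n_genes_in=cm.n_genes, n_genes_kept=kept.n_genes,
        thresholds={"min_count": min_count, "min_sample_frac": min_sample_frac},
    )
    logger.info("filter_genes: kept %d / %d genes (min_count=%d, min_frac=%.2f)",
                kept.n_genes, cm.n_genes, min_count, min_sample_frac)
    return kept, report


def batch_adjust(cm: CountMatrix, batches: Sequence[str], method: str = "none",
                 external: Callable[[CountMatrix, Sequence[str]], CountMatrix] | None = None,
                 ) -> CountMatrix:
    """Pluggable batch-integration stage on raw counts.

    ``none``: identity. ``median-center``: per gene, rescale each batch so
    its within-batch median matches the gene's global median (rounded to the
    nearest integer, floored at 0) — a location alignment sufficient for the
    downstream rank and correlation statistics. ``external``: delegate to a
    user-supplied callable (e.g. an empirical-Bayes adjuster run elsewhere)
    returning a matrix of identical shape.
    """
    batches = list(batches)
    if len(batches) != cm.n_samples:
        raise ValidationError("one batch label per sample required")
    if method == "none":
        return cm
    if method == "external":
        if external is None:
            raise ValidationError("method='external' requires an external callable")
        out = external(cm, batches)
        if out.counts.shape != cm.counts.shape:
            raise ValidationError("external batch adjuster changed the matrix shape")
        return out
    if method != "median-center":
        raise ValidationError(f"unknown batch method {method!r}")

    labels = np.asarray(batches)
    uniq, counts_per = np.unique(labels, return_counts=True)
    if np.any(counts_per < 2):
        small = uniq[counts_per < 2]
        raise ValidationError(f"median-center needs >= 2 samples per batch; got {list(small)}")
    values = cm.counts.astype(float)
    global_med = np.median(values, axis=1)
    adjusted = values.copy()
    for b in uniq:
        mask = labels == b
        batch_med = np.median(values[:, mask], axis=1)
        # genes silent in a batch (median 0) are left untouched there
        scale = np.divide(global_med, batch_med,
                          out=np.ones_like(global_med), where=batch_med > 0)
        adjusted[:, mask] = values[:, mask] * scale[:, np.newaxis]
    adjusted = np.maximum(0, np.rint(adjusted)).astype(np.int64)
    return CountMatrix(list(cm.gene_ids), list(cm.sample_ids), adjusted)
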