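"""Signature scoring of samples, pseudobulk replicates, or cells.

A unit's score for a signature is the mean (log-scale) expression of the
signature genes minus the mean of expression-matched control genes: all
genes are ranked by average expression and cut into ``n_bins`` equal-size
bins, and for every signature gene ``n_ctrl`` controls are drawn without
replacement from its bin. Subtracting bin-matched controls removes the
component of the score explained by overall expression level.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneSignature, NormalizedMatrix, ValidationError

__all__ = ["signature_score", "pseudobulk"]


def signature_score(expr: NormalizedMatrix, sig: GeneSignature, n_bins: int = 24,
                    n_ctrl: int = 100, seed: int = 0,
                    use_controls: bool = True) -> pd.DataFrame:
    """Per-unit control-subtracted signature score.

    ``expr`` is expected on a log scale. Returns a table with columns
    unit_id, signature, score. ``use_controls=False`` gives the plain
    signature-gene mean.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    present = [g for g in sig.gene_ids if g in set(expr.gene_ids)]
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    if len(present) < len(sig):
        warnings.warn(
            f"{len(sig) - len(present)} signature gene(s) absent from matrix; dropped")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    sig_rows = np.array([gene_pos[g] for g in present])
    sig_mean = expr.values[sig_rows].mean(axis=0)

    if not use_controls:
        scores = sig_mean
    else:
        rng = np.random.default_rng(seed)
        avg = expr.values.mean(axis=1)
        # rank genes by average expression, cut into equal-size bins
        order = np.argsort(avg, kind="stable")
        bin_of = np.empty(expr.n_genes, dtype=int)
        bin_of[order] = np.minimum(
            (np.arange(expr.n_genes) * n_bins) // expr.n_genes, n_bins - 1)
        ctrl_rows: set[int] = set()
        for row in sig_rows:
            pool = np.flatnonzero(bin_of == bin_of[row])
            take = min(n_ctrl, len(pool))
            ctrl_rows.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl_mean = expr.values[sorted(ctrl_rows)].mean(axis=0)
        scores = sig_mean - ctrl_mean

    return pd.DataFrame({"unit_id": expr.sample_ids, "signature": sig.name,
                         "score": scores})


def pseudobulk(expr: NormalizedMatrix, replicate_labels: Sequence[str],
               ) -> NormalizedMatrix:
    """Collapse per-cell columns into per-replicate gene-wise means."""
    labels = list(replicate_labels)
    if len(labels) != expr.n_samples:
        raise ValidationError("one replicate label per cell required")
    uniq = list(dict.fromkeys(labels))  # first-appearance order
    arr = np.asarray(labels)
    out = np.column_stack([expr.values[:, arr == r].mean(axis=1) for r in uniq])
    return NormalizedMatrix(list(expr.gene_ids), uniq, out)
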