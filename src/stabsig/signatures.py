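"""Responder / nonresponder gene-signature derivation.

Two routes, mirroring how such signatures are built in practice:

* two-group differential expression with a Wilcoxon rank-sum test,
  Bonferroni correction and top-k ranking by discriminatory power (the
  marker-gene style used for the mouse blood signatures), and
* per-gene Pearson correlation of expression against a continuous clinical
  outcome (C-peptide AUC %baseline, or months to diagnosis), with optional
  exclusion of genes that also track progression in the placebo arm, and
  cross-study intersection of the surviving gene sets.

Correlation p-values are deliberately left unadjusted: the signature
thresholds are raw per-gene significance cut-offs, not FDR-controlled
discovery sets.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import GeneSignature, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["wilcoxon_de", "top_k_signature", "pearson_with_p", "pearson_signature",
           "exclude_placebo_correlated", "combine_signatures", "wilcoxon_rank_sum"]


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both groups have <= 8 observations and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U statistic for group a, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=True)
    u = float(res.statistic)
    if u == len(a) * len(b) / 2.0:
        # complete rank symmetry between the groups: two-sided p is 1 by
        # definition (the continuity correction would otherwise nudge it below)
        return u, 1.0
    return u, float(res.pvalue)


def _standardized_u(u: float, n_a: int, n_b: int) -> float:
    """U centred and scaled under the null — the ranking statistic for top-k."""
    mu = n_a * n_b / 2.0
    sd = np.sqrt(n_a * n_b * (n_a + n_b + 1) / 12.0)
    return (u - mu) / sd


def wilcoxon_de(expr: NormalizedMatrix, group_a: Sequence[str], group_b: Sequence[str],
                min_detect_frac: float = 0.25, logfc_threshold: float = 0.0,
                ) -> pd.DataFrame:
    """Per-gene two-group Wilcoxon differential expression.

    A gene is tested only if it is detected (> 0) in at least
    ``min_detect_frac`` of group A or of group B, and if
    ``|log2_fc| >= logfc_threshold`` where
    ``log2_fc = log2((mean_A + 1) / (mean_B + 1))``. The Bonferroni
    adjustment multiplies by the number of genes actually tested.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    col = {s: i for i, s in enumerate(expr.sample_ids)}
    ia = [col[s] for s in group_a]
    ib = [col[s] for s in group_b]
    A = expr.values[:, ia]
    B = expr.values[:, ib]

    pct_a = (A > 0).mean(axis=1)
    pct_b = (B > 0).mean(axis=1)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    testable = ((pct_a >= min_detect_frac) | (pct_b >= min_detect_frac)) & (
        np.abs(log2_fc) >= logfc_threshold)

    rows = []
    for g in np.flatnonzero(testable):
        u, p = wilcoxon_rank_sum(A[g], B[g])
        rows.append((expr.gene_ids[g], log2_fc[g], u,
                     _standardized_u(u, len(ia), len(ib)), p, pct_a[g], pct_b[g]))
    de = pd.DataFrame(rows, columns=["gene_id", "log2_fc", "w_statistic",
                                     "w_standardized", "p_value",
                                     "pct_detected_A", "pct_detected_B"])
    n_tested = len(de)
    de["adjusted_p"] = np.minimum(1.0, de["p_value"] * n_tested)
    return de


def top_k_signature(de: pd.DataFrame, direction: str, k: int = 50,
                    alpha: float = 0.05, name: str | None = None) -> GeneSignature:
    """Top-k signature from a differential-expression table.

    Keeps genes significant after Bonferroni (``adjusted_p <= alpha``) whose
    fold-change sign matches ``direction``, ranks by |standardized W|
    (discriminatory power), breaking ties by larger |log2_fc| then gene id,
    and truncates to ``k``.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if len(de) == 0:
        raise ValidationError("empty differential-expression table")
    sign = 1.0 if direction == "positive" else -1.0
    cand = de[(de["adjusted_p"] <= alpha) & (np.sign(de["log2_fc"]) == sign)].copy()
    cand["_absw"] = cand["w_standardized"].abs()
    cand["_absfc"] = cand["log2_fc"].abs()
    cand = cand.sort_values(["_absw", "_absfc", "gene_id"],
                            ascending=[False, False, True], kind="stable")
    if len(cand) < k:
        warnings.warn(f"only {len(cand)} genes qualify for top-{k} {direction} signature")
    cand = cand.head(k)
    return GeneSignature(
        name=name or f"top{k}_{direction}",
        direction=direction,
        entries=cand.rename(columns={"w_standardized": "statistic"})[
            ["gene_id", "statistic", "p_value", "adjusted_p"]],
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t transform.

    ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom; |r| = 1
    gives p = 0. Pairs with a missing value in either vector are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValidationError("pearson_with_p needs >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _pearson_vectorized(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and p of a genes x samples block against one outcome."""
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Xc @ yc) / denom, -1.0, 1.0)
    r[denom == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def pearson_signature(expr: NormalizedMatrix, outcome: pd.Series | np.ndarray,
                      p_threshold: float = 0.05, name_prefix: str = "corr",
                      ) -> tuple[GeneSignature, GeneSignature]:
    """Split genes into positively / negatively outcome-correlated signatures.

    ``outcome`` is aligned by position to ``expr.sample_ids`` (or by index if
    a Series); samples with missing outcome are dropped. Thresholding uses
    the raw, unadjusted per-gene p-value. Each signature is ordered by
    ascending p, then descending |r|.
    """
    if isinstance(outcome, pd.Series):
        outcome = outcome.reindex(expr.sample_ids).to_numpy(dtype=float)
    else:
        outcome = np.asarray(outcome, dtype=float)
    ok = np.isfinite(outcome)
    if ok.sum() < 3:
        raise ValidationError("outcome non-missing for fewer than 3 samples")
    y = outcome[ok]
    if np.ptp(y) == 0:
        raise ValidationError("outcome is constant: correlations undefined")
    X = expr.values[:, ok]
    r, p = _pearson_vectorized(X, y)
    skipped = int(np.isnan(r).sum())
    if skipped:
        logger.warning("pearson_signature: %d constant gene(s) skipped", skipped)

    tbl = pd.DataFrame({"gene_id": expr.gene_ids, "statistic": r, "p_value": p,
                        "adjusted_p": np.nan}).dropna(subset=["statistic"])
    sigs = []
    for direction, mask in (("positive", tbl["statistic"] > 0),
                            ("negative", tbl["statistic"] < 0)):
        sel = tbl[mask & (tbl["p_value"] < p_threshold)].copy()
        sel["_absr"] = sel["statistic"].abs()
        sel = sel.sort_values(["p_value", "_absr", "gene_id"],
                              ascending=[True, False, True], kind="stable")
        sigs.append(GeneSignature(
            name=f"{name_prefix}_{direction}", direction=direction,
            entries=sel[["gene_id", "statistic", "p_value", "adjusted_p"]],
        ))
    return sigs[0], sigs[1]


def exclude_placebo_correlated(sig: GeneSignature, placebo_expr: NormalizedMatrix,
                               placebo_outcome: pd.Series | np.ndarray,
                               p_threshold: float = 0.05) -> GeneSignature:
    """Drop signature genes that track the outcome in the placebo arm.

    A gene is removed when its placebo-arm correlation has p < threshold in
    either direction; survivor order is preserved.
    """
    if isinstance(placebo_outcome, pd.Series):
        y = placebo_outcome.reindex(placebo_expr.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(placebo_outcome, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValidationError("placebo outcome non-missing for fewer than 3 samples")
    gene_pos = {g: i for i, g in enumerate(placebo_expr.gene_ids)}
    rows = [gene_pos[g] for g in sig.gene_ids if g in gene_pos]
    present = [g for g in sig.gene_ids if g in gene_pos]
    if rows:
        _, p = _pearson_vectorized(placebo_expr.values[np.ix_(rows, np.flatnonzero(ok))],
                                   y[ok])
        significant = {g for g, pv in zip(present, p) if np.isfinite(pv) and pv < p_threshold}
    else:
        significant = set()
    keep = ~sig.entries["gene_id"].isin(significant)
    return GeneSignature(name=f"{sig.name}_placebo_excluded", direction=sig.direction,
                         entries=sig.entries[keep])


def combine_signatures(sig_a: GeneSignature, sig_b: GeneSignature,
                       name: str | None = None) -> GeneSignature:
    """Intersection of two same-direction signatures.

    Genes are ordered by the mean of their (1-based) ranks in the two
    inputs, ties broken lexicographically; per-gene statistic and p carry
    over from ``sig_a``.
    """
    if sig_a.direction != sig_b.direction:
        raise ValidationError("cannot combine signatures of opposite direction")
    rank_a = {g: i + 1 for i, g in enumerate(sig_a.gene_ids)}
    rank_b = {g: i + 1 for i, g in enumerate(sig_b.gene_ids)}
    common = [g for g in rank_a if g in rank_b]
    order = sorted(common, key=lambda g: ((rank_a[g] + rank_b[g]) / 2.0, g))
    entries = sig_a.entries.set_index("gene_id").loc[order].reset_index()
    return GeneSignature(name=name or f"{sig_a.name}&{sig_b.name}",
                         direction=sig_a.direction, entries=entries)
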