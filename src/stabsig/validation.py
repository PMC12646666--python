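"""Response score and its subsampled ROC validation.

The response score of a sample is the weighted sum of its (standardized)
expression over the predictive-signature genes, the weights being the
signature's median model coefficients. Validation repeatedly draws small
subsets of the cohort, computes the ROC AUC of the score against the
responder label, and records the sensitivity/specificity at the cut point
maximizing Youden's J = sensitivity + specificity - 1. A fixed decision
threshold (default -0.01) yields per-study confusion counts.

Responders ("R") are the ROC positive class throughout; a sample is
classified responder iff score > threshold (strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import NormalizedMatrix, ValidationError
from .stability import PredictiveSignature

logger = logging.getLogger(__name__)

__all__ = ["response_score", "roc_auc", "youden_threshold", "ValidationSummary",
           "resampled_validation", "classify_fixed_threshold", "standardize_expression"]


def standardize_expression(expr: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene z-score across samples (population sd); constant genes -> 0."""
    v = expr.values
    sd = v.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (v - v.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0),
                 0.0)
    return NormalizedMatrix(list(expr.gene_ids), list(expr.sample_ids), z)


def response_score(expr: NormalizedMatrix, sig: PredictiveSignature,
                   meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Weighted-sum response score per sample.

    ``expr`` should be the standardized gene x sample matrix. Signature
    genes absent from the matrix are dropped (logged); all absent is an
    error. Study and response columns are merged in when metadata is given.
    """
    weights = sig.weights()
    present = [g for g in weights.index if g in set(expr.gene_ids)]
    if not present:
        raise ValidationError("no predictive-signature gene present in the matrix")
    if len(present) < len(weights):
        missing = sorted(set(weights.index) - set(present))
        logger.warning("response_score: %d signature gene(s) missing: %s",
                       len(missing), missing[:5])
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = np.array([gene_pos[g] for g in present])
    w = weights.loc[present].to_numpy()
    scores = w @ expr.values[rows]
    out = pd.DataFrame({"sample_id": expr.sample_ids, "score": scores})
    out.attrs["missing_genes"] = len(weights) - len(present)
    if meta is not None:
        out = out.merge(meta[["sample_id", "study", "response"]], on="sample_id",
                        how="left")
    return out


def _as_binary(labels: np.ndarray | pd.Series) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == "R").astype(float)
    return labels.astype(float)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation.

    AUC = P(score_R > score_NR) + 0.5 * P(equal), computed from midranks.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_threshold(scores: np.ndarray, labels: np.ndarray,
                     ) -> tuple[float, float, float, float]:
    """Cut point maximizing Youden's J over all midpoint thresholds.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus -inf and +inf; classification is responder iff
    score > threshold. Ties on J go to higher sensitivity, then lower
    threshold. Returns (threshold, sensitivity, specificity, J).
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("Youden threshold needs both classes present")
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best = None
    for thr in cands:
        pred = scores > thr
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec, j)
    _, thr, sens, spec, j = best
    return float(thr), sens, spec, float(j)


@dataclass
class ValidationSummary:
    auc_values: np.ndarray
    sensitivity_values: np.ndarray
    specificity_values: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.auc_values)
        for name in ("sensitivity_values", "specificity_values", "thresholds"):
            if len(getattr(self, name)) != n:
                raise ValidationError("summary vectors must have equal length")
        for name in ("auc_values", "sensitivity_values", "specificity_values"):
            v = getattr(self, name)
            if len(v) and (v.min() < 0 or v.max() > 1):
                raise ValidationError(f"{name} outside [0, 1]")

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity_values))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificity_values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, len(self.auc_values) + 1),
            "auc": self.auc_values, "sensitivity": self.sensitivity_values,
            "specificity": self.specificity_values, "threshold": self.thresholds,
        })


def resampled_validation(score_table: pd.DataFrame, n_iterations: int = 1000,
                         subset_size: int = 20, seed: int = 0,
                         max_redraw: int = 1000) -> ValidationSummary:
    """Subsampled ROC validation of the response score.

    Each iteration draws ``subset_size`` samples without replacement from
    the full scored cohort (redrawn, seeded, if single-class), computes the
    AUC and the Youden-optimal operating point, and the summary keeps the
    full distributions.
    """
    labeled = score_table[score_table["response"].isin(["R", "NR"])]
    scores = labeled["score"].to_numpy(dtype=float)
    y = _as_binary(labeled["response"].to_numpy())
    n = len(scores)
    if n < subset_size:
        raise ValidationError(f"cohort of {n} smaller than subset_size={subset_size}")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iterations)
    sens = np.empty(n_iterations)
    spec = np.empty(n_iterations)
    thr = np.empty(n_iterations)
    for it in range(n_iterations):
        for _ in range(max_redraw):
            idx = rng.choice(n, size=subset_size, replace=False)
            if 0 < y[idx].sum() < subset_size:
                break
        else:
            raise ValidationError("could not draw a two-class subset")
        aucs[it] = roc_auc(scores[idx], y[idx])
        thr[it], sens[it], spec[it], _ = youden_threshold(scores[idx], y[idx])
    return ValidationSummary(aucs, sens, spec, thr)


def classify_fixed_threshold(score_table: pd.DataFrame, threshold: float = -0.01,
                             group_by: str = "study") -> pd.DataFrame:
    """Confusion counts and FP/FN rates at a fixed threshold, per group + pooled.

    Predicted responder iff score > threshold. FN rate = FN / (FN + TP);
    FP rate = FP / (FP + TN).
    """
    labeled = score_table[score_table["response"].isin(["R", "NR"])].copy()
    labeled["pred_R"] = labeled["score"] > threshold
    rows = []
    groups = [("pooled", labeled)]
    if group_by in labeled.columns:
        groups += list(labeled.groupby(group_by, sort=True))
    for name, df in groups:
        is_r = df["response"] == "R"
        tp = int((is_r & df["pred_R"]).sum())
        fn = int((is_r & ~df["pred_R"]).sum())
        fp = int((~is_r & df["pred_R"]).sum())
        tn = int((~is_r & ~df["pred_R"]).sum())
        rows.append({
            "group": name, "tp": tp, "fn": fn, "fp": fp, "tn": tn,
            "fn_rate": fn / (fn + tp) if fn + tp else np.nan,
            "fp_rate": fp / (fp + tn) if fp + tn else np.nan,
        })
    return pd.DataFrame(rows)
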