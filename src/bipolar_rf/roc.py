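"""ROC discrimination with DeLong variance, confidence intervals and the paired test.

AUC is the midrank Mann–Whitney estimator (tied score pairs count one half).
Its variance follows the structural-component decomposition of DeLong et al.
(1988) in the fast midrank form of Sun & Xu (2014): per-positive components
V10 and per-negative components V01, with

    var(AUC) = var(V10)/m + var(V01)/n        (m positives, n negatives)

and the paired two-model test built from the 2x2 component covariance matrices.
95% confidence intervals are normal-approximation, clipped to [0, 1] — a
constant-score model therefore reports 0.500 with the degenerate interval
0.500–0.500 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateOutcomeError, InvalidInputError, SchemaError


@dataclass
class ROCResult:
    auc: float
    delong_variance: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


def _check_scores_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise SchemaError("scores and labels must be 1-d and of equal length")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("scores must be finite")
    if not np.all(np.isin(labels, (0, 1))):
        raise InvalidInputError("labels must be binary 0/1")
    labels = labels.astype(int)
    if labels.min() == labels.max():
        raise DegenerateOutcomeError("labels contain a single class")
    return scores, labels


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks of x (average rank over ties), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (per-positive) and V01 (per-negative) components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def roc_auc(scores, labels) -> ROCResult:
    """Midrank AUC with DeLong variance and clipped 95% CI.

    Requires at least one positive and one negative label; raises
    :class:`DegenerateOutcomeError` otherwise.
    """
    scores, labels = _check_scores_labels(np.asarray(scores, float), np.asarray(labels))
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    var01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = var10 / m + var01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(auc=auc, delong_variance=var, ci95=ci, n_pos=m, n_neg=n)


def paired_auc_variance(scores_a, scores_b, labels) -> float:
    """DeLong variance of AUC(a) - AUC(b) for two score vectors on the same
    labelled cases."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise SchemaError("paired score vectors must have equal length")
    _, labels_arr = _check_scores_labels(scores_a, np.asarray(labels))
    _, v10_a, v01_a = _delong_components(scores_a, labels_arr)
    _, v10_b, v01_b = _delong_components(scores_b, labels_arr)
    m, n = len(v10_a), len(v01_a)

    def _cov(u, v):
        if len(u) < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    return (
        _cov(v10_a, v10_a) + _cov(v10_b, v10_b) - 2 * _cov(v10_a, v10_b)
    ) / m + (
        _cov(v01_a, v01_a) + _cov(v01_b, v01_b) - 2 * _cov(v01_a, v01_b)
    ) / n


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Covariance-aware z-test of AUC(a) − AUC(b) on the same labelled cases.

    Returns (z, two-sided p).  When the variance of the difference vanishes the
    scores are rank-equivalent on this sample: an exact tie is reported as
    (0.0, 1.0); a zero-variance nonzero difference cannot arise from valid
    paired components and is reported with an infinite z and p = 0.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise SchemaError("paired score vectors must have equal length")
    _, labels_arr = _check_scores_labels(scores_a, np.asarray(labels))
    auc_a, _, _ = _delong_components(scores_a, labels_arr)
    auc_b, _, _ = _delong_components(scores_b, labels_arr)
    var_d = paired_auc_variance(scores_a, scores_b, labels_arr)
    diff = auc_a - auc_b
    if var_d <= 1e-15:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        return float(np.sign(diff)) * np.inf, 0.0
    z = diff / np.sqrt(var_d)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def operating_point(scores, labels, rule: str = "youden") -> tuple[float, float, float]:
    """Classification threshold on the score scale and its (sensitivity, specificity).

    ``rule="youden"`` scans every achievable threshold (predict positive when
    score >= t) and maximizes J = sens + spec − 1, breaking ties toward higher
    specificity (the larger threshold).  ``rule="prob0.5"`` fixes t = 0.5, for
    scores that are probabilities.  With all scores tied, youden degenerates to
    the all-negative point (sens 0, spec 1) by the tie-break.
    """
    scores, labels = _check_scores_labels(np.asarray(scores, float), np.asarray(labels))
    if rule == "prob0.5":
        t = 0.5
        return (t,) + _sens_spec(scores, labels, t)
    if rule != "youden":
        raise InvalidInputError(f"unknown operating-point rule {rule!r}")
    # candidate thresholds: each distinct score, plus one above the maximum
    cands = np.unique(scores)
    cands = np.append(cands, cands[-1] + 1.0)
    best = None
    for t in cands:
        sens, spec = _sens_spec(scores, labels, t)
        j = sens + spec - 1.0
        # tie-break toward higher specificity, then the larger threshold
        key = (j, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return float(t), float(sens), float(spec)


def _sens_spec(scores: np.ndarray, labels: np.ndarray, t: float) -> tuple[float, float]:
    pred = scores >= t
    pos = labels == 1
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens, spec
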