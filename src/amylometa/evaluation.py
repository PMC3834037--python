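"""Predictor assessment: confusion metrics, ROC/AUC, DeLong, bootstrap, thresholds.

Conventions used throughout:

- a score is called positive when it is >= the threshold (ties positive);
- partial AUC is reported unnormalised, so a perfect classifier scores
  exactly the band width (0.2 on the 0-20% false-positive-rate band);
- metrics with a zero denominator come back as ``nan`` and their names are
  listed in :attr:`ClassificationMetrics.undefined`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import RegionAnnotation

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "ROCCurve",
    "AUCResult",
    "confusion_from_scores",
    "classification_metrics",
    "roc_curve",
    "auc",
    "concordance_auc",
    "partial_auc",
    "delong_compare",
    "auc_with_ci",
    "bootstrap_ci",
    "select_threshold",
    "per_residue_confusion",
]


# ---------------------------------------------------------------------------
# Confusion matrices and scalar metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Scalar summaries of a confusion matrix.

    acc, sensitivity, specificity and q are proportions in [0,1]; mcc is in
    [-1,1]. Metrics whose denominator is zero are ``nan`` and named in
    ``undefined``.
    """

    acc: float
    sensitivity: float
    specificity: float
    mcc: float
    q: float
    f1: float
    undefined: frozenset[str] = field(default_factory=frozenset)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """acc, sensitivity, specificity, MCC, Q=(sens+spec)/2 and F1 from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    mcc_den = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / mcc_den if mcc_den > 0 else float("nan")
    q = (sens + spec) / 2.0
    f1 = _ratio(2.0 * cm.tp, 2.0 * cm.tp + cm.fp + cm.fn)
    undefined = frozenset(
        name
        for name, v in [
            ("sensitivity", sens),
            ("specificity", spec),
            ("mcc", mcc),
            ("q", q),
            ("f1", f1),
        ]
        if math.isnan(v)
    )
    return ClassificationMetrics(acc, sens, spec, mcc, q, f1, undefined)


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if len(scores) != len(labels):
        raise ValueError(f"{len(scores)} scores but {len(labels)} labels")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion_from_scores(scores, labels, threshold: float) -> ConfusionMatrix:
    """Threshold scores (>= threshold is positive) and count against labels."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() in (0, len(labels)):
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


# ---------------------------------------------------------------------------
# ROC, AUC, partial AUC


@dataclass(frozen=True)
class ROCCurve:
    """ROC points ordered by descending threshold; tied scores are grouped.

    ``thresholds[0]`` is +inf (nothing called positive); the curve starts at
    (FPR, TPR) = (0, 0) and ends at (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def roc_curve(scores, labels) -> ROCCurve:
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() in (0, len(labels)):
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr)


def auc(scores, labels=None) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the tie-aware Mann-Whitney concordance
    P(score+ > score-) + 0.5 P(tie) (see :func:`concordance_auc`).
    Accepts either a fitted :class:`ROCCurve` or ``(scores, labels)``.
    """
    roc = scores if isinstance(scores, ROCCurve) else roc_curve(scores, labels)
    return float(np.trapezoid(roc.tpr, roc.fpr))


def concordance_auc(scores, labels) -> float:
    """AUC via pairwise concordance (midrank form of the Mann-Whitney statistic)."""
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def partial_auc(
    scores, labels, fpr_lo: float = 0.0, fpr_hi: float = 0.2, normalized: bool = False
) -> float:
    """Area of the ROC restricted to FPR in [fpr_lo, fpr_hi].

    Unnormalised by default, so a perfect curve scores the band width;
    ``normalized=True`` divides by the band width. Curve values at the band
    edges are obtained by linear interpolation.
    """
    if not 0.0 <= fpr_lo < fpr_hi <= 1.0:
        raise ValueError(f"invalid FPR band [{fpr_lo}, {fpr_hi}]")
    roc = scores if isinstance(scores, ROCCurve) else roc_curve(scores, labels)
    fpr, tpr = roc.fpr, roc.tpr
    inside = (fpr > fpr_lo) & (fpr < fpr_hi)
    # Interpolate the TPR where the band edges cut the curve. A vertical ROC
    # segment exactly at an edge needs care: the area to the RIGHT of the edge
    # starts at the segment's top (the curve leaves rightward from there),
    # while the area to the LEFT ends at the segment's bottom (the curve
    # arrives there before climbing). Hence upper envelope at fpr_lo, lower
    # envelope at fpr_hi.
    lo_tpr = _edge_tpr(fpr, tpr, fpr_lo, "upper")
    hi_tpr = _edge_tpr(fpr, tpr, fpr_hi, "lower")
    xs = np.concatenate([[fpr_lo], fpr[inside], [fpr_hi]])
    ys = np.concatenate([[lo_tpr], tpr[inside], [hi_tpr]])
    area = float(np.trapezoid(ys, xs))
    return area / (fpr_hi - fpr_lo) if normalized else area


def _edge_tpr(fpr: np.ndarray, tpr: np.ndarray, x: float, envelope: str) -> float:
    """TPR of a (possibly vertically-jumping) ROC curve at FPR value ``x``."""
    left = int(np.searchsorted(fpr, x, side="left"))
    right = int(np.searchsorted(fpr, x, side="right")) - 1
    if right >= left:  # x coincides with one or more curve points
        return float(tpr[left] if envelope == "lower" else tpr[right])
    return float(np.interp(x, fpr, tpr))


# ---------------------------------------------------------------------------
# DeLong test and confidence intervals


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # V10[i] = P-hat(pos_i > neg) with ties counted half
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    theta = float(v10.mean())
    return v10, v01, theta


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    diff: float
    z: float
    p_value: float


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test for the difference of two correlated AUCs on paired scores.

    Returns the two AUCs, their difference (A - B), the normal z statistic and
    the two-sided p-value. A zero-variance difference is p = 1 when the AUCs
    coincide and an error otherwise.
    """
    a, labels = _check_scores_labels(scores_a, labels)
    b, labels_b = _check_scores_labels(scores_b, labels)
    if labels.sum() in (0, len(labels)):
        raise ValueError("both classes must be present")
    va10, va01, theta_a = _placements(a, labels)
    vb10, vb01, theta_b = _placements(b, labels)
    m, n = len(va10), len(va01)
    diff = theta_a - theta_b
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 observations per class")
    d10 = va10 - vb10
    d01 = va01 - vb01
    var = d10.var(ddof=1) / m + d01.var(ddof=1) / n
    if var <= 0:
        if abs(diff) < 1e-12:
            return DeLongResult(theta_a, theta_b, 0.0, 0.0, 1.0)
        raise ValueError("zero estimated variance with a nonzero AUC difference")
    z = diff / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return DeLongResult(theta_a, theta_b, diff, z, min(p, 1.0))


@dataclass(frozen=True)
class AUCResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str


def auc_with_ci(
    scores,
    labels,
    level: float = 0.95,
    method: str = "delong-variance",
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCResult:
    """AUC with a confidence interval (DeLong asymptotic variance or bootstrap)."""
    scores, labels = _check_scores_labels(scores, labels)
    est = concordance_auc(scores, labels)
    if method == "delong-variance":
        v10, v01, theta = _placements(scores, labels)
        var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        zq = float(norm.ppf(0.5 + level / 2.0))
        half = zq * math.sqrt(max(var, 0.0))
        return AUCResult(est, max(0.0, theta - half), min(1.0, theta + half), method)
    if method == "bootstrap":
        lo, hi = bootstrap_ci(
            lambda s, l: concordance_auc(s, l), scores, labels,
            n_boot=n_boot, level=level, seed=seed,
        )
        return AUCResult(est, lo, hi, method)
    raise ValueError(f"unknown method {method!r}")


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of (scores, labels).

    Resampling is stratified within each class so every replicate keeps both
    classes and the original class sizes; reproducible from ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores, labels = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        stats[b] = statistic(scores[idx], labels[idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Threshold selection


def select_threshold(
    scores, labels, criterion: str = "upper-left", target: float | None = None
) -> float:
    """Choose a decision threshold from labelled scores.

    Criteria:

    - ``upper-left``: minimise the Euclidean distance to the (0,1) corner of
      the ROC, sqrt((1-sens)^2 + (1-spec)^2);
    - ``youden``: maximise J = sens + spec - 1;
    - ``high-sensitivity``: the largest threshold with sens >= ``target``;
    - ``high-specificity``: the smallest threshold with spec >= ``target``.

    Candidate thresholds are the distinct score values plus +inf (nothing
    positive). Optimisation ties are broken toward the larger (more specific)
    threshold.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() in (0, len(labels)):
        raise ValueError("both classes must be present")
    if criterion in ("high-sensitivity", "high-specificity"):
        if target is None or not 0.0 < target < 1.0:
            raise ValueError(f"criterion {criterion!r} needs a target in (0,1)")
    cand = np.concatenate([[np.inf], np.unique(scores)[::-1]])  # descending
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    sens = np.array([np.sum(scores[pos] >= t) / m for t in cand])
    spec = np.array([np.sum(scores[~pos] < t) / n for t in cand])

    if criterion == "upper-left":
        obj = np.hypot(1.0 - sens, 1.0 - spec)
        return float(cand[int(np.argmin(obj))])  # argmin keeps the largest threshold on ties
    if criterion == "youden":
        obj = sens + spec - 1.0
        return float(cand[int(np.argmax(obj))])
    if criterion == "high-sensitivity":
        ok = np.flatnonzero(sens >= target)
        if len(ok) == 0:
            raise ValueError(f"sensitivity target {target} unreachable")
        return float(cand[ok[0]])  # largest threshold meeting it
    if criterion == "high-specificity":
        ok = np.flatnonzero(spec >= target)
        if len(ok) == 0:
            raise ValueError(f"specificity target {target} unreachable")
        return float(cand[ok[-1]])  # smallest threshold meeting it
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# Per-residue region evaluation


def per_residue_confusion(
    predicted: Sequence[RegionAnnotation],
    truth: Sequence[RegionAnnotation],
    seq_len: int,
) -> ConfusionMatrix:
    """Residue-level confusion between predicted and experimentally validated
    regions on one sequence: each of the ``seq_len`` residues is classified by
    membership in the union of predicted vs true regions, so the four counts
    sum to ``seq_len``. Sum matrices over proteins for a batched evaluation."""
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")

    def mask(regions: Sequence[RegionAnnotation]) -> np.ndarray:
        m = np.zeros(seq_len, dtype=bool)
        for r in regions:
            if r.end > seq_len:
                raise ValueError(
                    f"region {r.start}-{r.end} exceeds sequence length {seq_len}"
                )
            m[r.start - 1 : r.end] = True
        return m

    p, t = mask(predicted), mask(truth)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )
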