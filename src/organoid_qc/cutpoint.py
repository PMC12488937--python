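"""Youden-optimal single-parameter cutpoints.

For each feature an ROC curve is built over candidate thresholds placed at
midpoints between consecutive sorted unique values (plus +/-inf
sentinels), the orientation is auto-chosen so AUC >= 0.5, and the optimal
threshold maximizes Youden's J = sensitivity + specificity - 1.  The
winning parameter in day-30 brain-organoid cohorts is the Feret diameter:
organoids below the threshold classify as High quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import AgreementMetrics, agreement_metrics
from .errors import DomainError

__all__ = [
    "RocCurve",
    "CutpointResult",
    "roc_curve",
    "youden_optimal_cutpoint",
    "classify_by_threshold",
]

# direction semantics: which side of the threshold is called "High" quality
HIGH_FEATURE_LOW_QUALITY = "high_feature=>Low"  # large value = low quality (Feret)
HIGH_FEATURE_HIGH_QUALITY = "high_feature=>High"


@dataclass
class RocCurve:
    thresholds: np.ndarray  # midpoints with -inf/+inf sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str
    auc: float


@dataclass
class CutpointResult:
    feature: str
    optimal_threshold: float
    youden_j: float
    direction: str
    agreement: AgreementMetrics | None = None

    def as_dict(self) -> dict:
        out = {
            "feature": self.feature,
            "optimal_threshold": self.optimal_threshold,
            "youden_j": self.youden_j,
            "direction": self.direction,
        }
        if self.agreement is not None:
            out["agreement"] = self.agreement.as_dict()
        return out


def _check_inputs(feature, labels) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise DomainError("feature and label lengths differ")
    pos = y == "High"
    if pos.all() or (~pos).all():
        raise DomainError("both classes must be present")
    return x, pos


def roc_curve(feature, expert_labels) -> RocCurve:
    """ROC of a single feature against the binary expert rating.

    Candidate thresholds are midpoints between consecutive sorted unique
    feature values, with -inf and +inf sentinels.  The direction is chosen
    so the oriented AUC is >= 0.5.
    """
    x, pos = _check_inputs(feature, expert_labels)
    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    # orientation "high_feature=>Low": predict High when x < t
    se = np.array([(pos & (x < t)).sum() / n_pos for t in thresholds])
    sp = np.array([((~pos) & (x >= t)).sum() / n_neg for t in thresholds])
    auc = float(np.trapezoid(se, 1.0 - sp))
    if auc >= 0.5:
        return RocCurve(thresholds, se, sp, HIGH_FEATURE_LOW_QUALITY, auc)
    # flip: predict High when x >= t
    return RocCurve(thresholds, 1.0 - se, 1.0 - sp, HIGH_FEATURE_HIGH_QUALITY, 1.0 - auc)


def youden_optimal_cutpoint(roc: RocCurve, feature_name: str = "") -> CutpointResult:
    """Threshold maximizing J = Se + Sp - 1.

    Ties are broken toward higher specificity, then the smaller threshold.
    Infinite-sentinel winners are replaced by the adjacent finite midpoint
    when one exists.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    order = np.lexsort((roc.thresholds, -roc.specificity, -j))
    best = order[0]
    thr = float(roc.thresholds[best])
    if not np.isfinite(thr):
        finite = roc.thresholds[np.isfinite(roc.thresholds)]
        if len(finite):
            thr = float(finite[0] if thr < 0 else finite[-1])
    return CutpointResult(
        feature=feature_name,
        optimal_threshold=thr,
        youden_j=float(j[best]),
        direction=roc.direction,
    )


def classify_by_threshold(
    feature,
    threshold: float,
    direction: str = HIGH_FEATURE_LOW_QUALITY,
    expert_labels=None,
) -> tuple[np.ndarray, AgreementMetrics | None]:
    """Dichotomize a feature at a threshold into High/Low quality calls.

    For ``high_feature=>Low`` (the Feret convention): value < threshold is
    High quality, value >= threshold is Low.  Values exactly at the
    threshold therefore classify as Low.  When expert labels are given the
    2x2 agreement is returned alongside.
    """
    if not np.isfinite(threshold) and not np.isinf(threshold):
        raise DomainError("threshold must not be NaN")
    x = np.asarray(feature, dtype=float)
    if direction == HIGH_FEATURE_LOW_QUALITY:
        labels = np.where(x < threshold, "High", "Low")
    elif direction == HIGH_FEATURE_HIGH_QUALITY:
        labels = np.where(x >= threshold, "High", "Low")
    else:
        raise DomainError(f"unknown direction {direction!r}")
    agreement = None if expert_labels is None else agreement_metrics(labels, expert_labels)
    return labels, agreement


def cutpoint_for_feature(table, feature: str, label_col: str = "expert_label") -> CutpointResult:
    """Convenience: ROC + Youden cutpoint + threshold agreement for one column."""
    roc = roc_curve(table[feature], table[label_col])
    result = youden_optimal_cutpoint(roc, feature)
    _, result.agreement = classify_by_threshold(
        table[feature], result.optimal_threshold, result.direction, table[label_col]
    )
    return result
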