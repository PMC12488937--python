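"""Unsupervised two-group clustering and agreement with the expert rating.

The selected features are z-score normalized; the cluster number is chosen
by the elbow of the within-cluster sum of squares (WSS) over k = 1..15
(deterministic surrogate for the visual elbow: the k maximizing the second
difference of WSS, restricted to k > 1); k-means runs with 20 random
starts under a fixed seed (default 111).  Agreement with the expert
High/Low rating is reported as PPV/NPV/sensitivity/specificity with High
as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DomainError

__all__ = [
    "ElbowProfile",
    "ClusterAssignment",
    "AgreementMetrics",
    "zscore_normalize",
    "elbow_wss",
    "kmeans_cluster",
    "map_clusters_to_labels",
    "agreement_metrics",
]


@dataclass
class ElbowProfile:
    k_values: np.ndarray
    wss: np.ndarray
    chosen_k: int


@dataclass
class ClusterAssignment:
    cluster_id: np.ndarray  # values in {1, 2}
    mapped_label: np.ndarray | None = None  # "High"/"Low" after mapping
    wss: float = float("nan")


@dataclass
class AgreementMetrics:
    """2x2 agreement between a High/Low prediction and the expert rating."""

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)

    def __post_init__(self) -> None:
        def rate(num, den):
            return num / den if den else None

        self.ppv = rate(self.tp, self.tp + self.fp)
        self.npv = rate(self.tn, self.tn + self.fn)
        self.sensitivity = rate(self.tp, self.tp + self.fn)
        self.specificity = rate(self.tn, self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "ppv": self.ppv,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def zscore_normalize(table: pd.DataFrame | np.ndarray, features: list[str] | None = None):
    """Column-wise z-scores: mean 0, sample SD (ddof=1) of 1."""
    if isinstance(table, pd.DataFrame):
        X = table[features].to_numpy(dtype=float) if features else table.to_numpy(dtype=float)
        names = features or list(table.columns)
    else:
        X = np.asarray(table, dtype=float)
        names = [str(i) for i in range(X.shape[1])]
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [n for n, s in zip(names, sd) if s == 0]
        raise DomainError(f"zero-variance feature(s): {bad}")
    return (X - X.mean(axis=0)) / sd


def _fit_kmeans(X: np.ndarray, k: int, n_start: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, init="random", n_init=n_start, random_state=seed, algorithm="lloyd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatters about memory leaks on MKL
        km.fit(X)
    return km


def elbow_wss(
    matrix: np.ndarray, k_max: int = 15, n_start: int = 20, seed: int = 111
) -> ElbowProfile:
    """WSS over k = 1..k_max; elbow = argmax of the WSS second difference.

    Each WSS is the best (lowest) of ``n_start`` k-means runs.  The chosen
    k is restricted to 2..k_max-1 so the second difference is defined.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] <= k_max:
        raise DomainError(f"need more than {k_max} rows for the elbow scan")
    ks = np.arange(1, k_max + 1)
    wss = np.empty(len(ks))
    for i, k in enumerate(ks):
        if k == 1:
            wss[i] = float(((X - X.mean(axis=0)) ** 2).sum())
        else:
            wss[i] = float(_fit_kmeans(X, int(k), n_start, seed).inertia_)
    second_diff = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]  # indexed by k = 2..k_max-1
    chosen_k = int(ks[1:-1][np.argmax(second_diff)])
    return ElbowProfile(ks, wss, chosen_k)


def kmeans_cluster(
    matrix: np.ndarray, k: int = 2, n_start: int = 20, seed: int = 111
) -> ClusterAssignment:
    """Best-of-n_start k-means partition; cluster ids are 1-based."""
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise DomainError("k must be >= 2")
    if X.shape[0] < k:
        raise DomainError("need at least as many rows as clusters")
    km = _fit_kmeans(X, k, n_start, seed)
    return ClusterAssignment(cluster_id=km.labels_ + 1, wss=float(km.inertia_))


def map_clusters_to_labels(
    assignment: ClusterAssignment,
    expert_labels,
    feret: np.ndarray | None = None,
) -> ClusterAssignment:
    """Map the two cluster ids onto High/Low.

    The cluster with the higher proportion of expert-High organoids maps
    to High; an exact tie is broken toward the cluster with the smaller
    mean Feret diameter (high quality = small organoid).
    """
    ids = np.asarray(assignment.cluster_id)
    labels = np.asarray(expert_labels)
    if set(np.unique(ids)) != {1, 2}:
        raise DomainError("expected exactly two non-empty clusters")
    high = labels == "High"
    prop1, prop2 = high[ids == 1].mean(), high[ids == 2].mean()
    if prop1 > prop2:
        high_cluster = 1
    elif prop2 > prop1:
        high_cluster = 2
    elif feret is not None:
        feret = np.asarray(feret, dtype=float)
        high_cluster = 1 if feret[ids == 1].mean() <= feret[ids == 2].mean() else 2
    else:
        high_cluster = 1
    mapped = np.where(ids == high_cluster, "High", "Low")
    return ClusterAssignment(cluster_id=ids, mapped_label=mapped, wss=assignment.wss)


def agreement_metrics(predicted, expert) -> AgreementMetrics:
    """PPV/NPV/Se/Sp of a High/Low prediction vs the expert rating.

    High is the positive class.  An empty predicted-positive (or
    -negative) margin leaves the corresponding rate as None with a warning.
    """
    pred = np.asarray(predicted)
    true = np.asarray(expert)
    if pred.shape != true.shape:
        raise DomainError("label vectors differ in length")
    p_pos, t_pos = pred == "High", true == "High"
    tp = int((p_pos & t_pos).sum())
    fp = int((p_pos & ~t_pos).sum())
    tn = int((~p_pos & ~t_pos).sum())
    fn = int((~p_pos & t_pos).sum())
    metrics = AgreementMetrics(tp, fp, tn, fn)
    if metrics.ppv is None:
        warnings.warn("no predicted positives: PPV undefined", stacklevel=2)
    if metrics.npv is None:
        warnings.warn("no predicted negatives: NPV undefined", stacklevel=2)
    return metrics
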