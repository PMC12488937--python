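"""Point-biserial feature screen against the expert quality rating.

Each of the nine morphological parameters is correlated with the binary
expert label (High = 1, Low = 0); p-values from the t transform are
FDR-adjusted (Benjamini-Hochberg) across the nine features, and a feature
is selected when p_adj < p_cut and |r| > r_cut.  With the default
stringency (p_cut = 1e-5, r_cut = 0.5) this reproduces the five-parameter
panel: Feret diameter, area, perimeter, cyst count, cyst-area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .morphometry import FEATURE_COLUMNS

__all__ = ["ScreenResult", "point_biserial", "fdr_adjust", "screen_features", "pca_embed"]

LABEL_ENCODING = {"High": 1, "Low": 0}


@dataclass
class ScreenResult:
    """Per-feature screen outcome, ordered by |r| descending."""

    table: pd.DataFrame  # columns: feature, r_pb, p_raw, p_adj, selected
    p_cut: float
    r_cut: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table.selected, "feature"])


def _encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        unknown = set(np.unique(arr)) - set(LABEL_ENCODING)
        if unknown:
            raise DomainError(f"unknown labels {sorted(unknown)}; expected High/Low")
        arr = np.vectorize(LABEL_ENCODING.get)(arr)
    arr = arr.astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise DomainError("labels must be binary (High/Low or 0/1)")
    return arr


def point_biserial(feature, label) -> tuple[float, float]:
    """Point-biserial correlation of a numeric feature with a binary label.

    Equals the Pearson correlation with a 0/1 encoding; the two-sided
    p-value comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    x = np.asarray(feature, dtype=float)
    y = _encode_labels(label)
    if len(x) != len(y):
        raise DomainError("feature and label lengths differ")
    if y.min() == y.max():
        raise DomainError("labels contain a single class: correlation undefined")
    if np.ptp(x) == 0:
        raise DomainError("feature has zero variance: correlation undefined")
    res = stats.pointbiserialr(y, x)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    label_col: str = "expert_label",
    p_cut: float = 1e-5,
    r_cut: float = 0.5,
) -> ScreenResult:
    """Screen all features of a cohort table against the expert rating."""
    features = list(features or [c for c in FEATURE_COLUMNS if c in table.columns])
    if not features:
        raise DomainError("no feature columns found")
    labels = table[label_col]
    rows = []
    for feat in features:
        r, p = point_biserial(table[feat], labels)
        rows.append({"feature": feat, "r_pb": r, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = fdr_adjust(out["p_raw"].to_numpy())
    out["selected"] = (out.p_adj < p_cut) & (out.r_pb.abs() > r_cut)
    out = out.sort_values("r_pb", key=np.abs, ascending=False, ignore_index=True)
    return ScreenResult(out, p_cut, r_cut)


def pca_embed(table: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """First two principal components of the z-scored features.

    Visualization convenience only.  Constant features are dropped with a
    warning.  Returns ``(coords, explained_variance_ratio)``.
    """
    import warnings

    if len(features) < 2:
        raise DomainError("need at least 2 features for a 2-D embedding")
    X = table[features].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        X = X[:, keep]
    if X.shape[1] < 2:
        raise DomainError("fewer than 2 non-constant features")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=2, svd_solver="full")
    return pca.fit_transform(Z), pca.explained_variance_ratio_
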