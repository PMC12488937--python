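"""Bulk-expression cell-type composition and cohort statistics.

Per-sample cell-type fractions are estimated by non-negative least squares
of library-size-normalized expression (counts per million, no log) on the
columns of a reference signature matrix, renormalized to the simplex — a
deliberately simple, deterministic deconvolution.  Cohort statistics link
the mesenchymal-cell (MC) fraction to morphology and quality: per-line
coefficients of variation, Wilcoxon rank-sum group comparisons and rank
correlations (MC vs Feret diameter, marker MFIs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .errors import DomainError

__all__ = [
    "CompositionEstimate",
    "CohortCompositionStats",
    "estimate_fractions",
    "cv_summary",
    "group_difference_test",
    "rank_correlation",
    "coefficient_of_variation",
]

MESENCHYMAL = "mesenchymal"


@dataclass
class CompositionEstimate:
    """Per-sample simplex fraction vectors (samples x cell types)."""

    fractions: pd.DataFrame

    @property
    def mesenchymal_fraction(self) -> pd.Series:
        return self.fractions[MESENCHYMAL]


@dataclass
class CohortCompositionStats:
    per_line_cv: pd.Series  # CV (%) of MC fraction within each line
    median_line_cv: float
    cv_of_line_means: float
    group_tests: dict  # grouping name -> {"p": ..., "direction": ...}
    correlations: dict  # name -> {"r": ..., "p": ..., "method": ...}


# ---------------------------------------------------------------------------
# Deconvolution


def _align(bulk: pd.DataFrame, signature: pd.DataFrame, exclusion: set[str]) -> tuple:
    shared = [g for g in signature.index if g in set(bulk.columns) and g not in exclusion]
    if len(shared) < 50:
        raise DomainError(f"only {len(shared)} shared genes after exclusion; need >= 50")
    return bulk[shared], signature.loc[shared]


def estimate_fractions(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    exclusion_list=(),
) -> CompositionEstimate:
    """NNLS deconvolution of bulk samples against a cell-type signature.

    Parameters
    ----------
    bulk:
        samples x genes non-negative expression table.
    signature:
        genes x cell-types non-negative reference; must contain a
        "mesenchymal" column.
    exclusion_list:
        gene ids removed before fitting (mitochondrial/ribosomal/sex-
        chromosome/MALAT1 lists in the intended application).

    Each sample is normalized to counts per million before the fit (making
    the estimate invariant to per-sample scale) and regressed on the raw
    signature columns; the non-negative coefficients are renormalized to
    sum to 1.
    """
    if (signature.to_numpy() < 0).any():
        raise DomainError("signature must be non-negative")
    if (signature.sum(axis=0) == 0).any():
        raise DomainError("signature contains an all-zero cell-type column")
    B, S = _align(bulk, signature, set(exclusion_list))
    S_mat = S.to_numpy(dtype=float)
    rows = {}
    for sample_id, expr in B.iterrows():
        x = expr.to_numpy(dtype=float)
        total = x.sum()
        if total <= 0:
            raise DomainError(f"sample {sample_id!r} has zero total expression")
        coef, _ = nnls(S_mat, x / total * 1e6)
        if coef.sum() == 0:
            raise DomainError(f"sample {sample_id!r}: degenerate NNLS solution")
        rows[sample_id] = coef / coef.sum()
    return CompositionEstimate(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(signature.columns))
    )


# ---------------------------------------------------------------------------
# Cohort statistics


def coefficient_of_variation(values) -> float:
    """CV = SD / mean x 100, with the sample (n-1) SD."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(v.std(ddof=1) / mean * 100.0)


def cv_summary(mc_fraction, line_ids) -> tuple[pd.Series, float, float]:
    """Per-line CV of the MC fraction, their median, and the CV of line means.

    A line whose mean fraction is 0 gets a missing (NaN) CV.
    """
    df = pd.DataFrame({"mc": np.asarray(mc_fraction, dtype=float), "line": np.asarray(line_ids)})
    counts = df.groupby("line").size()
    if (counts < 2).any():
        raise DomainError("every line needs >= 2 samples for a CV")
    per_line = df.groupby("line")["mc"].apply(coefficient_of_variation)
    line_means = df.groupby("line")["mc"].mean()
    return per_line, float(per_line.median()), coefficient_of_variation(line_means)


def group_difference_test(values, groups) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of a quantity between two groups.

    Exact null distribution when both groups have <= 25 samples and the
    data are tie-free; otherwise the normal approximation with tie
    correction.  Returns the p-value and the direction (which group has
    the larger median).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    names = np.unique(g)
    if len(names) != 2:
        raise DomainError(f"need exactly two groups, got {list(names)}")
    a, b = v[g == names[0]], v[g == names[1]]
    has_ties = len(np.unique(v)) < len(v)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = f"{names[0]} > {names[1]}"
    elif med_b > med_a:
        direction = f"{names[1]} > {names[0]}"
    else:
        direction = "equal medians"
    return {"p": float(res.pvalue), "direction": direction, "method": method}


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman (default) or Pearson correlation with its p-value.

    Spearman uses average ranks for ties with the p-value from the t
    transform; it is the statistic reported for the MC-Feret association.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise DomainError("need equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("constant vector: correlation undefined")
    if method == "spearman":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    raise DomainError(f"unknown method {method!r}")


def cohort_composition_stats(
    table: pd.DataFrame,
    mc_col: str = f"frac_{MESENCHYMAL}",
    feret_col: str = "feret_um",
    groupings: dict | None = None,
    mfi_cols: tuple = ("mfi_CD105", "mfi_CD73"),
    section_feret_col: str = "section_feret_um",
) -> CohortCompositionStats:
    """All cohort-level composition statistics from one flat table.

    ``groupings`` maps a name (e.g. "expert", "cluster", "feret") to a
    column of two-level group labels.
    """
    per_line, median_cv, cv_means = cv_summary(table[mc_col], table["line_id"])
    tests = {
        name: group_difference_test(table[mc_col], table[col])
        for name, col in (groupings or {}).items()
    }
    corr: dict = {}
    r, p = rank_correlation(table[mc_col], table[feret_col])
    corr["mc_vs_feret"] = {"r": r, "p": p, "method": "spearman"}
    a, b = mfi_cols
    if a in table.columns and b in table.columns:
        r, p = rank_correlation(table[a], table[b])
        corr["cd105_vs_cd73_mfi"] = {"r": r, "p": p, "method": "spearman"}
        if section_feret_col in table.columns:
            for col, key in ((a, "cd105_mfi_vs_section_feret"), (b, "cd73_mfi_vs_section_feret")):
                r, p = rank_correlation(table[col], table[section_feret_col])
                corr[key] = {"r": r, "p": p, "method": "spearman"}
    return CohortCompositionStats(per_line, median_cv, cv_means, tests, corr)
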