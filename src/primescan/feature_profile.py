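"""Molecular feature comparison of primed versus active enhancers.

Elements are annotated with a binary matrix over features — overlap with
ChIP/histone peak sets plus motif presence — and per-class feature
percentages are compared by ordinary least-squares regression of the
primed-class percentages on the active-class percentages (one point per
feature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .genomic_core import GenomicInterval, find_overlaps

__all__ = ["FeatureMatrix", "RegressionResult", "build_feature_matrix",
           "feature_proportions", "proportion_regression"]

CLASSES = ("primed", "active_enhancer")


@dataclass
class FeatureMatrix:
    """Binary element x feature matrix with a per-element class label."""

    values: pd.DataFrame  # elements x features, 0/1
    classes: pd.Series  # element -> "primed" | "active_enhancer"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.classes.index):
            raise ValueError("matrix rows and class labels must share an index")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        vals = self.values.values
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix must be binary")
        bad = set(self.classes) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class label(s): {sorted(bad)}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def build_feature_matrix(
    elements: Mapping[str, GenomicInterval],
    classes: Mapping[str, str],
    feature_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    motif_matrix: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Overlap-based binary annotation of elements.

    A ChIP/histone feature column is 1 iff the element overlaps >= 1
    interval of that peak set; motif columns from ``motif_matrix`` are
    appended unchanged. Feature names must not collide with motif ids.
    """
    if not elements:
        raise ValueError("empty element set")
    eids = sorted(elements)
    feature_names = sorted(feature_peak_sets)
    if motif_matrix is not None:
        clash = set(feature_names) & set(motif_matrix.columns)
        if clash:
            raise ValueError(f"feature names collide with motif ids: {sorted(clash)}")
    mat = pd.DataFrame(0, index=eids, columns=feature_names, dtype=int)
    queries = [elements[e] for e in eids]
    for name in feature_names:
        hits = find_overlaps(queries, list(feature_peak_sets[name]))
        for qi, _ in hits:
            mat.iloc[qi, mat.columns.get_loc(name)] = 1
    if motif_matrix is not None:
        missing = [e for e in eids if e not in motif_matrix.index]
        if missing:
            raise ValueError(f"motif matrix missing elements: {missing}")
        mat = pd.concat([mat, motif_matrix.loc[eids].astype(int)], axis=1)
    labels = pd.Series({e: classes[e] for e in eids})
    return FeatureMatrix(mat, labels)


def feature_proportions(matrix: FeatureMatrix, cls: str) -> pd.Series:
    """Percentage of the class's elements carrying each feature."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    sub = matrix.values[matrix.classes == cls]
    if sub.empty:
        raise ValueError(f"class {cls!r} has no elements")
    return 100.0 * sub.mean(axis=0)


def proportion_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """OLS of primed-class percentages (y) on active-class percentages (x).

    Returns slope, intercept, R-squared and the two-sided p-value of the
    slope (t statistic, n - 2 df). Requires >= 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired feature points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sp_stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(float(res.slope), float(res.intercept), r2,
                            float(res.pvalue))
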