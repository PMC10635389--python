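"""Reference thresholds, distribution comparisons, distance statistics and the
PCA composite phenotyping index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point
from statsmodels.stats.multitest import multipletests

EXACT_KS_PRODUCT = 10_000
MIN_REFERENCE_CELLS = 20


@dataclass
class ThresholdSpec:
    reference_group: str
    channel: str
    k: float
    threshold: float
    n_reference: int


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_x: int
    n_y: int


@dataclass
class CompositeIndex:
    features: list[str]
    loadings: np.ndarray          # features x components
    scores: np.ndarray            # samples x components
    variance_explained: np.ndarray
    means: np.ndarray
    sds: np.ndarray


@dataclass
class GroupComparison:
    f_statistic: float
    p_anova: float
    comparisons: pd.DataFrame     # group, t, p_raw, p_adj vs reference
    reference: str


def derive_threshold(
    reference: np.ndarray, k: float = 2.0, *, reference_group: str = "",
    channel: str = ""
) -> ThresholdSpec:
    """Positivity threshold = mean + k·SD of a reference distribution.

    Needs at least 20 finite reference values; SD uses ddof=1.
    """
    v = np.asarray(reference, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < MIN_REFERENCE_CELLS:
        raise ValueError("insufficient reference: need >= 20 finite values")
    if k <= 0:
        raise ValueError("k must be > 0")
    thr = float(v.mean() + k * v.std(ddof=1))
    return ThresholdSpec(reference_group, channel, k, thr, int(v.size))


def ks_two_sample(x, y) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the sup of |ECDF_x − ECDF_y| over the pooled support; the p-value is
    exact when n_x·n_y ≤ 10 000 and asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in KS input")
    method = "exact" if x.size * y.size <= EXACT_KS_PRODUCT else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return KSResult(float(res.statistic), float(res.pvalue), x.size, y.size)


def distance_to_polyline(points, polyline) -> np.ndarray:
    """Minimum distance from each point to a polyline (µm)."""
    line = np.asarray(polyline, dtype=float)
    if line.ndim != 2 or line.shape[0] < 2:
        raise ValueError("polyline needs >= 2 vertices")
    ls = LineString(line)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([ls.distance(Point(p)) for p in pts])


def signed_midline_offset(points, midline, toward) -> np.ndarray:
    """Signed distance to a midline: positive on the side of ``toward``.

    ``toward`` is a reference polyline (e.g. the ventricle edge) defining the
    positive side. Magnitude equals the unsigned midline distance.
    """
    d = distance_to_polyline(points, midline)
    mid = LineString(np.asarray(midline, dtype=float))
    ref = LineString(np.asarray(toward, dtype=float))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    signs = np.empty(len(pts))
    for i, p in enumerate(pts):
        foot = mid.interpolate(mid.project(Point(p)))
        # a point is on the positive side when it sits nearer the reference
        # line than its perpendicular foot on the midline does
        signs[i] = 1.0 if ref.distance(Point(p)) < ref.distance(foot) else -1.0
    return signs * d


def composite_pca_index(features: pd.DataFrame) -> CompositeIndex:
    """Composite phenotyping index: z-score features, eigendecompose.

    Rows are samples (per-mouse summaries), columns features. Component signs
    are fixed so the largest-magnitude loading of each PC is positive.
    """
    if features.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if features.shape[1] < 2:
        raise ValueError("need >= 2 features")
    if features.isna().any().any():
        raise ValueError("missing values in feature table")
    X = features.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.nonzero(sds == 0)[0]
    if constant.size:
        names = [features.columns[i] for i in constant]
        raise ValueError(f"constant feature(s): {names}")
    Z = (X - means) / sds
    cov = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1
    scores = Z @ evecs
    return CompositeIndex(
        features=list(features.columns),
        loadings=evecs,
        scores=scores,
        variance_explained=evals / evals.sum(),
        means=means,
        sds=sds,
    )


def group_compare(
    values, groups, reference: str, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA plus vs-reference t-tests with Holm correction.

    All-constant input (F undefined) reports F=0, p=1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if reference not in labels:
        raise ValueError(f"reference group absent: {reference}")
    samples = {g: values[groups == g] for g in labels}
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g} has n < 2")
    if np.all(values == values[0]):
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(*samples.values())
        f_stat, p_anova = float(f_stat), float(p_anova)
    others = [g for g in labels if g != reference]
    rows = []
    for g in others:
        a, b = samples[g], samples[reference]
        if np.all(np.concatenate([a, b]) == a[0]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({"group": g, "t": float(t), "p_raw": float(p)})
    comp = pd.DataFrame(rows)
    if len(comp):
        comp["p_adj"] = multipletests(comp["p_raw"], alpha=alpha, method="holm")[1]
    else:
        comp["p_adj"] = []
    return GroupComparison(f_stat, p_anova, comp, reference)


def ecdf_report(
    values, groups, n_bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group ECDF on the pooled grid plus fixed-width histogram bins.

    Returns (ecdf table: group, value, ecdf) and (histogram table: group,
    bin_left, bin_right, count); histogram counts sum to each group's n.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    grid = np.unique(values)
    ecdf_rows = []
    for g in pd.unique(groups):
        v = np.sort(values[groups == g])
        if v.size == 0:
            raise ValueError(f"empty group: {g}")
        heights = np.searchsorted(v, grid, side="right") / v.size
        ecdf_rows.append(pd.DataFrame({"group": g, "value": grid, "ecdf": heights}))
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, lo + 1.0])
    hist_rows = []
    for g in pd.unique(groups):
        v = values[groups == g]
        counts, _ = np.histogram(v, bins=edges)
        hist_rows.append(pd.DataFrame({
            "group": g, "bin_left": edges[:-1], "bin_right": edges[1:],
            "count": counts,
        }))
    return pd.concat(ecdf_rows, ignore_index=True), pd.concat(hist_rows, ignore_index=True)


__all__ = [
    "ThresholdSpec", "KSResult", "CompositeIndex", "GroupComparison",
    "derive_threshold", "ks_two_sample", "distance_to_polyline",
    "signed_midline_offset", "composite_pca_index", "group_compare",
    "ecdf_report",
]
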