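"""Relating singular value vectors to sample classes, features, and views.

Four questions come up once a decomposition is in hand:

* does a sample vector track the known sample classes?
  (:func:`categorical_regression_test` — class-means model F-test)
* which individual feature profiles follow a given template vector?
  (:func:`template_correlations` — per-feature Pearson r with BH-adjusted
  t-transform P-values)
* how should heterogeneous feature profiles be overlaid on one template?
  (:func:`scale_shift_fit` — per-feature linear fit a_i*x + b_i, then
  :func:`groupwise_timepoint_test` on the fitted values per time point)
* which vectors pair up across views?
  (:func:`upgma_pair` — average-linkage clustering at distance -|r|)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .selection import MIN_P, bh_adjust

__all__ = [
    "ClassLabels",
    "ScaleShiftFit",
    "PairingResult",
    "categorical_regression_test",
    "template_correlations",
    "scale_shift_fit",
    "groupwise_timepoint_test",
    "upgma_pair",
]


@dataclass
class ClassLabels:
    """Categorical class membership per sample."""

    sample_ids: list[str]
    classes: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.classes = list(map(str, self.classes))
        if len(self.sample_ids) != len(self.classes):
            raise ValueError("one class per sample required")

    @property
    def n_classes(self) -> int:
        return len(set(self.classes))


@dataclass
class RegressionTest:
    p: float
    f_stat: float
    r_squared: float
    df_between: int
    df_within: int


@dataclass
class ScaleShiftFit:
    """Per-feature linear map onto a template: fitted = a_i*profile + b_i."""

    slope: np.ndarray
    intercept: np.ndarray
    fitted: np.ndarray  # (features x concatenated axis)
    degenerate: np.ndarray  # constant profiles: a=0, b=mean(template)


@dataclass
class PairingResult:
    labels: list[str]
    distance: np.ndarray  # square matrix of -|Pearson r|
    merge_tree: np.ndarray  # scipy linkage matrix (average linkage)
    pairs: list[tuple[str, str]]  # leaf pairs that merge directly


def categorical_regression_test(
    v: Sequence[float], labels: ClassLabels
) -> RegressionTest:
    """F-test of the class-means (categorical regression) model.

    Fits ``v_j = C0 + sum_S C1_S * delta_Sj`` by least squares and tests it
    against the intercept-only model; identical to one-way ANOVA.  P-values
    of perfect fits are reported as the minimal positive float.
    """
    v = np.asarray(v, dtype=float)
    groups = np.asarray(labels.classes)
    if v.size != groups.size:
        raise ValueError("vector length must equal sample count")
    uniq = np.unique(groups)
    k, n = uniq.size, v.size
    if k < 2:
        raise ValueError("need at least 2 classes")
    if n <= k:
        raise ValueError("need more samples than classes")
    grand = v.mean()
    ssb = sum(
        (v[groups == g].size) * (v[groups == g].mean() - grand) ** 2
        for g in uniq
    )
    ssw = sum(((v[groups == g] - v[groups == g].mean()) ** 2).sum()
              for g in uniq)
    sst = ssb + ssw
    r2 = 0.0 if sst == 0 else ssb / sst
    df1, df2 = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return RegressionTest(1.0, 0.0, 0.0, df1, df2)
        return RegressionTest(MIN_P, np.inf, 1.0, df1, df2)
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return RegressionTest(max(p, MIN_P) if p < 1 else p, float(f), r2,
                          df1, df2)


def template_correlations(
    template: Sequence[float], profiles: np.ndarray
) -> pd.DataFrame:
    """Pearson r of every feature profile with a template vector.

    Raw P-values come from the t transform ``t = r*sqrt((n-2)/(1-r^2))``
    (two-sided); the BH adjustment is applied over the testable features.
    Zero-variance profiles have undefined r and are flagged and excluded
    from the adjustment (r, p, p_adj reported as NaN).
    """
    t_vec = np.asarray(template, dtype=float)
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = t_vec.size
    if X.shape[1] != n:
        raise ValueError("profiles and template lengths differ")
    if n < 3:
        raise ValueError("need at least 3 points for a correlation test")
    tc = t_vec - t_vec.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    t_ss = (tc**2).sum()
    x_ss = (Xc**2).sum(axis=1)
    if t_ss == 0:
        raise ValueError("template has zero variance")
    excluded = x_ss == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ tc) / np.sqrt(x_ss * t_ss)
    r = np.clip(r, -1.0, 1.0)
    r[excluded] = np.nan
    p = np.full(r.shape, np.nan)
    ok = ~excluded
    r_ok = r[ok]
    with np.errstate(divide="ignore"):
        tstat = r_ok * np.sqrt((n - 2) / np.maximum(1 - r_ok**2, 0))
    p_ok = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p_ok = np.where(np.abs(r_ok) >= 1, MIN_P, np.maximum(p_ok, MIN_P))
    p[ok] = np.minimum(p_ok, 1.0)
    p_adj = np.full(r.shape, np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(p[ok])
    return pd.DataFrame(
        {"r": r, "p": p, "p_adj": p_adj, "excluded": excluded}
    )


def scale_shift_fit(
    template: Sequence[float], profiles: np.ndarray
) -> ScaleShiftFit:
    """Least-squares map of each feature profile onto the template.

    Each feature has its own baseline and amplitude; before overlaying
    profiles on a common template they are scaled and shifted by regressing
    ``template = a_i * profile_i + b_i`` over the full concatenated
    condition/time axis (one shared a_i, b_i per feature).  Constant
    profiles get a=0, b=mean(template) and are flagged.
    """
    t_vec = np.asarray(template, dtype=float)
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    if X.shape[1] != t_vec.size:
        raise ValueError("profiles and template lengths differ")
    xm = X.mean(axis=1)
    xc = X - xm[:, None]
    var = (xc**2).sum(axis=1)
    degenerate = var == 0
    cov = xc @ (t_vec - t_vec.mean())
    slope = np.zeros(X.shape[0])
    np.divide(cov, var, out=slope, where=~degenerate)
    intercept = t_vec.mean() - slope * xm
    fitted = slope[:, None] * X + intercept[:, None]
    return ScaleShiftFit(slope, intercept, fitted, degenerate)


def groupwise_timepoint_test(
    fits: ScaleShiftFit | np.ndarray,
    groups: Sequence[str],
    times: Sequence,
) -> pd.DataFrame:
    """Group differences at each time point across the fitted profiles.

    ``groups`` and ``times`` label the columns of the fitted-value matrix
    (the concatenated condition/time axis).  At each time point, the fitted
    values of all features in one group are compared against the other
    group(s): a two-sided pooled two-sample t test for 2 groups, the
    class-means regression F-test for 3 or more.
    """
    fitted = fits.fitted if isinstance(fits, ScaleShiftFit) else np.asarray(fits)
    fitted = np.atleast_2d(fitted)
    groups = np.asarray([str(g) for g in groups])
    times = np.asarray(list(times))
    if groups.size != fitted.shape[1] or times.size != fitted.shape[1]:
        raise ValueError("groups/times must label every fitted column")
    rows = []
    for t in pd.unique(times):
        at_t = times == t
        g_at_t = groups[at_t]
        uniq = pd.unique(g_at_t)
        if uniq.size < 2:
            raise ValueError(f"time point {t!r}: fewer than 2 groups")
        samples = [fitted[:, at_t][:, g_at_t == g].ravel() for g in uniq]
        if any(s.size < 2 for s in samples):
            raise ValueError(f"time point {t!r}: a group has < 2 values")
        if uniq.size == 2:
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
            kind = "t"
        else:
            flat = np.concatenate(samples)
            lbls = np.concatenate(
                [np.repeat(g, s.size) for g, s in zip(uniq, samples)]
            )
            res = categorical_regression_test(
                flat, ClassLabels(list(map(str, range(flat.size))), list(lbls))
            )
            stat, p = res.f_stat, res.p
            kind = "F"
        if np.isnan(p):  # zero variance in both groups, identical means
            stat, p = 0.0, 1.0
        rows.append({"time": t, "statistic": float(stat), "test": kind,
                     "p": float(p)})
    return pd.DataFrame(rows)


def upgma_pair(vectors: Mapping[str, Sequence[float]]) -> PairingResult:
    """Average-linkage (UPGMA) clustering of vectors at distance -|r|.

    The distance between two vectors is the negative absolute Pearson
    correlation, so |r| = 1 pairs merge first (distance -1) regardless of
    sign.  ``pairs`` lists merges of two original vectors — the mutual
    first-choice partners used to read off cross-view component pairings.
    """
    labels = list(vectors)
    if len(labels) < 2:
        raise ValueError("need at least 2 vectors")
    X = np.array([np.asarray(vectors[k], dtype=float) for k in labels])
    if np.any(X.std(axis=1) == 0):
        bad = [labels[i] for i in np.flatnonzero(X.std(axis=1) == 0)]
        raise ValueError(f"zero-variance vector(s): {bad}")
    r = np.corrcoef(X)
    dist = -np.abs(r)
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices(len(labels), k=1)
    tree = linkage(dist[iu], method="average")
    n = len(labels)
    pairs = [
        (labels[int(a)], labels[int(b)])
        for a, b, _, _ in tree
        if a < n and b < n
    ]
    return PairingResult(labels, dist, tree, pairs)
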