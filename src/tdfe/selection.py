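"""Chi-squared outlier feature extraction on singular value vectors.

Features are scored against the null hypothesis that their entries in the
chosen factor columns (singular value vectors or PC scores) are draws from a
normal distribution.  The per-feature statistic

    score_i = sum_l (U[i, l] / sigma_l)^2

(sigma_l = standard deviation of column l over all features) is referred to
the chi-squared distribution with df = number of components; the upper-tail
P-values are Benjamini-Hochberg adjusted and features with adjusted P below
alpha are the extracted outliers.  Component indices are 1-based throughout,
matching the l notation of the decomposition outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SelectionResult",
    "chi2_pvalues",
    "bh_adjust",
    "select_outliers",
    "intersect_selections",
]

#: Stand-in for an exact zero P-value, keeping BH and sorting well-defined.
MIN_P = float(np.finfo(float).tiny)


@dataclass
class SelectionResult:
    feature_ids: list[str]
    score: np.ndarray
    df: int
    p: np.ndarray
    p_adj: np.ndarray
    selected: np.ndarray
    alpha: float
    components: tuple[int, ...]

    @property
    def selected_ids(self) -> set[str]:
        return {f for f, s in zip(self.feature_ids, self.selected) if s}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "score": self.score,
                "df": self.df,
                "p": self.p,
                "p_adj": self.p_adj,
                "selected": self.selected,
            }
        )


def _columns(U: np.ndarray, components: Sequence[int]) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be a (features x components) matrix")
    comps = tuple(int(c) for c in components)
    if not comps:
        raise ValueError("components must be non-empty")
    for c in comps:
        if c < 1 or c > U.shape[1]:
            raise ValueError(
                f"component {c} out of range 1..{U.shape[1]} (1-based)"
            )
    return U[:, [c - 1 for c in comps]]


def chi2_pvalues(
    U: np.ndarray, components: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature chi-squared scores and raw upper-tail P-values.

    ``components`` are 1-based column indices of ``U``.  sigma_l is the
    (mean-centred, ddof=1) standard deviation of column l across features;
    the score divides raw entries by sigma_l without centring, per the
    outlier statistic's definition — factor columns are near zero-mean, so
    the distinction is negligible in practice.
    """
    cols = _columns(U, components)
    sigma = cols.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = [components[i] for i in np.flatnonzero(sigma == 0)]
        raise ValueError(f"zero-variance factor column(s): {bad}")
    score = ((cols / sigma) ** 2).sum(axis=1)
    p = stats.chi2.sf(score, df=cols.shape[1])
    p = np.where(p <= 0, MIN_P, p)
    return score, p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("raw P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_outliers(
    U: np.ndarray,
    components: Sequence[int] = (1, 2, 3, 4, 5),
    alpha: float = 0.01,
    feature_ids: Sequence[str] | None = None,
) -> SelectionResult:
    """Chi-squared/BH outlier extraction on the given factor columns.

    Defaults follow the standard protocol: first five components, adjusted
    P < 0.01.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    comps = tuple(int(c) for c in components)
    score, p = chi2_pvalues(U, comps)
    p_adj = bh_adjust(p)
    selected = p_adj < alpha
    n = score.size
    ids = (list(map(str, feature_ids)) if feature_ids is not None
           else [f"f{i + 1}" for i in range(n)])
    if len(ids) != n:
        raise ValueError("feature_ids length mismatch")
    return SelectionResult(
        feature_ids=ids,
        score=score,
        df=len(comps),
        p=p,
        p_adj=p_adj,
        selected=selected,
        alpha=float(alpha),
        components=comps,
    )


def intersect_selections(results: Iterable[SelectionResult]) -> set[str]:
    """IDs selected in every one of the given selection results."""
    results = list(results)
    if not results:
        raise ValueError("need at least one selection result")
    out = results[0].selected_ids
    for r in results[1:]:
        out &= r.selected_ids
    return out
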