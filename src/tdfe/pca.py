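"""PCA-based unsupervised feature extraction (single-view baseline).

Instead of embedding samples, this PCA embeds the *features*: with columns
standardized (zero mean, sum of squares N), the gram matrix ``G = X @ X.T``
is eigendecomposed, ``G u_k = lambda_k u_k``.  The eigenvector entry
``u_k[i]`` is feature i's k-th PC score; the PC loadings over samples are
``v_k = X.T @ u_k`` (eigenvectors of the covariance matrix ``X.T X`` scaled
by singular values).  Outlier features on the leading score columns are then
extracted with the same chi-squared/BH machinery as the tensor route,
optionally after screening components for significant sample-class
dependence.

Computed through the SVD of X rather than the N x N gram matrix for
stability and memory; the equivalence is asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .association import ClassLabels, categorical_regression_test
from .hosvd import _fix_signs
from .selection import SelectionResult, select_outliers
from .tensors import ViewMatrix

__all__ = ["PCAResult", "pca_decompose", "pca_unsupervised_fe"]


@dataclass
class PCAResult:
    scores: np.ndarray  # (features x k): u_k columns
    loadings: np.ndarray  # (samples x k): v_k = X^T u_k
    eigenvalues: np.ndarray  # lambda_k, non-increasing
    feature_ids: list[str]
    sample_ids: list[str]


def pca_decompose(X: ViewMatrix, n_components: int | None = None) -> PCAResult:
    """Gram-matrix PCA on features, via the SVD of X.

    ``X = U S V^T`` gives scores ``u_k`` (columns of U, unit eigenvectors of
    ``X X^T``), eigenvalues ``lambda_k = s_k^2``, and loadings
    ``v_k = X^T u_k = s_k V[:, k]``.  The caller is expected to pass a
    column-standardized matrix.  Sign convention matches the tensor
    decomposition (largest-|entry| positive per column).
    """
    vals = X.values
    kmax = min(vals.shape)
    k = kmax if n_components is None else int(n_components)
    if k < 1 or k > kmax:
        raise ValueError(f"n_components must lie in 1..{kmax}")
    U, s, _ = np.linalg.svd(vals, full_matrices=False)
    U = _fix_signs(U[:, :k])
    loadings = vals.T @ U
    return PCAResult(
        scores=U,
        loadings=loadings,
        eigenvalues=s[:k] ** 2,
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
    )


def pca_unsupervised_fe(
    X: ViewMatrix,
    screen_labels: ClassLabels | None = None,
    components: Sequence[int] = (1, 2, 3, 4, 5),
    alpha: float = 0.01,
    screen_alpha: float = 0.05,
) -> tuple[SelectionResult, list[int]]:
    """PCA-based unsupervised FE: screen components, then chi-squared/BH.

    If class labels are given, only components whose loadings show
    significant sample-class dependence (categorical-regression P below
    ``screen_alpha``) enter the chi-squared score; the rest are dropped.
    Returns the selection result and the surviving (1-based) component list.

    Raises ``ValueError`` if no component survives the screen.
    """
    comps = [int(c) for c in components]
    res = pca_decompose(X, n_components=max(comps))
    if screen_labels is not None:
        kept = [
            c for c in comps
            if categorical_regression_test(
                res.loadings[:, c - 1], screen_labels
            ).p < screen_alpha
        ]
        if not kept:
            raise ValueError(
                "no PC loading passed the categorical-regression screen; "
                "no components available for feature extraction"
            )
    else:
        kept = comps
    sel = select_outliers(
        res.scores, components=kept, alpha=alpha, feature_ids=X.feature_ids
    )
    return sel, kept
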