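"""Higher-order SVD (HOSVD) of a product tensor.

The Tucker expansion used here writes an m-mode tensor as

    x[n1,...,nm] = sum_{l1..lm} G(l1,...,lm) * prod_k U_k[nk, lk]

where each factor matrix ``U_k`` has orthonormal columns (the mode's
*singular value vectors*) and ``G`` is the core tensor.  HOSVD fixes the
otherwise overcomplete expansion by taking ``U_k`` as the top left singular
vectors of the mode-k unfolding and ``G`` as the tensor contracted with every
``U_k`` transposed.  Core entries with large |G| mark strongly coupled
combinations of per-mode components — that coupling, read off the core
ranking, is how feature vectors are matched to sample vectors downstream.

A Type II tensor lacks the shared mode entirely; its per-view sample (Case I)
or feature (Case II) vectors are recovered by projecting each view's factor
columns back through that view's data matrix (:func:`project_missing_mode`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tensors import (
    CASE_SHARED_SAMPLES,
    MultiViewSet,
    MultiwayArray,
)

__all__ = [
    "HOSVDResult",
    "CoreRanking",
    "ProjectedVectors",
    "hosvd_decompose",
    "reconstruct",
    "rank_core",
    "project_missing_mode",
]

DEFAULT_RANK = 10

# Unfoldings taller than this aspect ratio go through the Gram matrix
# (A @ A.T eigendecomposition) instead of a full SVD: same left singular
# vectors, much cheaper when prod(other modes) >> mode size.
_GRAM_ASPECT = 4


@dataclass
class HOSVDResult:
    core: np.ndarray
    factors: list[np.ndarray]  # one (mode size x rank) matrix per mode
    ranks: tuple[int, ...]
    mode_labels: list[str]
    singular_values: list[np.ndarray]  # per-mode unfolding singular values
    tensor_type: str = "type1"
    case: str = CASE_SHARED_SAMPLES
    mode_ids: Sequence[Sequence[str]] = ()


@dataclass
class CoreRanking:
    """Core entries sorted by decreasing |G|, 1-based indices."""

    entries: list[tuple[tuple[int, ...], float]]


@dataclass
class ProjectedVectors:
    """Per-view singular value vectors over the mode a Type II tensor lacks.

    ``vectors[name]`` is a (rank x shared-mode length) matrix: row l is the
    l-th projected sample (Case I) or feature (Case II) vector of that view.
    """

    vectors: dict[str, np.ndarray]
    shared_ids: list[str]
    derivation: str


def _unfold(values: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k unfolding: mode-k fibers as rows, other modes in cyclic order."""
    m = values.ndim
    order = [mode] + [(mode + 1 + i) % m for i in range(m - 1)]
    return np.transpose(values, order).reshape(values.shape[mode], -1)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-|entry| positive (ties -> first index)."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _mode_svd(A: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-`rank` left singular vectors and singular values of A."""
    n, p = A.shape
    if p > _GRAM_ASPECT * n:
        w, V = np.linalg.eigh(A @ A.T)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        return V[:, order[:rank]], np.sqrt(w[:rank])
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    return U[:, :rank], s[:rank]


def multi_mode_dot(values: np.ndarray, mats: Sequence[np.ndarray],
                   transpose: bool = False) -> np.ndarray:
    """Contract `values` with one matrix per mode (U or U^T on every mode)."""
    out = values
    for k, M in enumerate(mats):
        M = M.T if transpose else M
        out = np.moveaxis(np.tensordot(M, out, axes=(1, k)), 0, k)
    return out


def hosvd_decompose(
    T: MultiwayArray | np.ndarray,
    ranks: Sequence[int] | int | None = None,
) -> HOSVDResult:
    """Plain HOSVD: one SVD per mode unfolding, no iterative refinement.

    Parameters
    ----------
    T
        The tensor (a :class:`MultiwayArray` or a bare ndarray).
    ranks
        Per-mode truncation; a single int is broadcast.  Defaults to
        min(mode size, 10) per mode.

    The returned factors carry a deterministic sign convention (each
    column's largest-magnitude entry is positive), and components within a
    mode are ordered by decreasing unfolding singular value.
    """
    if isinstance(T, MultiwayArray):
        values = T.values
        labels = list(T.mode_labels)
        ttype, case, mode_ids = T.tensor_type, T.case, T.mode_ids
    else:
        values = np.asarray(T, dtype=float)
        labels = [f"mode{k}" for k in range(values.ndim)]
        ttype, case, mode_ids = "type1", CASE_SHARED_SAMPLES, ()

    shape = values.shape
    if ranks is None:
        ranks = [min(n, DEFAULT_RANK) for n in shape]
    elif np.isscalar(ranks):
        ranks = [min(n, int(ranks)) for n in shape]
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != values.ndim:
        raise ValueError(f"{len(ranks)} ranks for a {values.ndim}-mode tensor")
    for k, (r, n) in enumerate(zip(ranks, shape)):
        if r < 1 or r > n:
            raise ValueError(f"rank {r} invalid for mode {k} of size {n}")

    factors, svals = [], []
    for k in range(values.ndim):
        U, s = _mode_svd(_unfold(values, k), ranks[k])
        factors.append(_fix_signs(U))
        svals.append(s)
    core = multi_mode_dot(values, factors, transpose=True)
    return HOSVDResult(
        core=core,
        factors=factors,
        ranks=ranks,
        mode_labels=labels,
        singular_values=svals,
        tensor_type=ttype,
        case=case,
        mode_ids=mode_ids,
    )


def reconstruct(res: HOSVDResult) -> np.ndarray:
    """Multiply the core back through all factors (exact at full ranks)."""
    return multi_mode_dot(res.core, res.factors, transpose=False)


def rank_core(res: HOSVDResult, top_n: int = 10) -> CoreRanking:
    """Core entries ranked by decreasing |G(l1,...,lm)|.

    Ties are broken by lexicographic index order; indices are reported
    1-based to match the component numbering used everywhere else.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    core = res.core
    flat_idx = [tuple(int(i) + 1 for i in idx)
                for idx in np.ndindex(core.shape)]
    vals = core.ravel()
    order = sorted(range(vals.size), key=lambda i: (-abs(vals[i]), flat_idx[i]))
    top = order[: min(top_n, vals.size)]
    return CoreRanking([(flat_idx[i], float(vals[i])) for i in top])


def project_missing_mode(
    res: HOSVDResult, mset: MultiViewSet
) -> ProjectedVectors:
    """Per-view singular value vectors for the mode a Type II tensor lacks.

    Case I (shared samples): the l-th sample vector of view k is
    ``sum_i U_k[i, l] * X_k[i, j]`` over samples j — each view's factor
    columns pushed through its own data matrix.  Case II swaps roles and
    yields per-view feature vectors.  There are m such vector sets (one per
    view), unlike a Type I decomposition whose shared-mode factor is unique.
    """
    if res.tensor_type != "type1" and res.tensor_type != "type2":
        raise ValueError(f"unknown tensor type {res.tensor_type!r}")
    if res.tensor_type == "type1":
        raise ValueError(
            "project_missing_mode applies to Type II results only; a Type I "
            "tensor already carries the shared-mode factor"
        )
    if len(res.factors) != mset.m:
        raise ValueError("factor count does not match number of views")
    out: dict[str, np.ndarray] = {}
    for k, view in enumerate(mset.views):
        U = res.factors[k]
        if mset.case == CASE_SHARED_SAMPLES:
            if U.shape[0] != view.n_features:
                raise ValueError(
                    f"factor {k} rows != features of view {view.name!r}"
                )
            out[view.name] = U.T @ view.values  # (rank x samples)
        else:
            if U.shape[0] != view.n_samples:
                raise ValueError(
                    f"factor {k} rows != samples of view {view.name!r}"
                )
            out[view.name] = U.T @ view.values.T  # (rank x features)
    tag = ("sample vectors via U_k^T X_k"
           if mset.case == CASE_SHARED_SAMPLES
           else "feature vectors via U_k^T X_k^T")
    return ProjectedVectors(out, mset.shared_ids, tag)
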