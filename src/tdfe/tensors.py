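"""Multi-view matrices and their product tensors.

A *view* is one data modality (e.g. mRNA or miRNA expression) stored as a
features x samples matrix.  Multiple views either share their samples
(Case I, e.g. several omics layers measured on the same specimens) or share
their features (Case II, e.g. the same genes measured under different
treatments).

Two product tensors can be formed from ``m`` views:

* **Type I** — the (m+1)-mode tensor of entry-wise products, one feature per
  view at each shared index:  ``x[i1,...,im,j] = prod_k X_k[i_k, j]``
  (Case I; Case II swaps feature/sample roles).
* **Type II** — the m-mode tensor obtained by summing Type I over the shared
  mode: ``x~[i1,...,im] = sum_j prod_k X_k[i_k, j]``.  For two views this is
  simply the matrix product ``X1 @ X2.T``.

Type II trades the shared mode for an M-fold (Case I) reduction in memory,
which is what makes genome-scale problems tractable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ViewMatrix",
    "MultiViewSet",
    "MultiwayArray",
    "standardize",
    "build_type1",
    "build_type2",
    "DEFAULT_ELEMENT_CAP",
]

#: Default cap on dense Type I tensor size (elements).  Memory and time for
#: Type I grow like M * prod_k N_k; beyond this, use a Type II tensor.
DEFAULT_ELEMENT_CAP = 200_000_000

CASE_SHARED_SAMPLES = "shared_samples"
CASE_SHARED_FEATURES = "shared_features"


class DegenerateColumnError(ValueError):
    """A sample column has zero variance and cannot be standardized."""


class ElementCapError(MemoryError):
    """The requested dense Type I tensor would exceed the element cap."""


@dataclass
class ViewMatrix:
    """One view: a features x samples matrix with row and column IDs."""

    values: np.ndarray
    feature_ids: Sequence[str]
    sample_ids: Sequence[str]
    name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"view {self.name!r}: values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"view {self.name!r}: non-finite values present")
        self.feature_ids = list(map(str, self.feature_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        n, m = self.values.shape
        if len(self.feature_ids) != n:
            raise ValueError(
                f"view {self.name!r}: {len(self.feature_ids)} feature IDs "
                f"for {n} rows"
            )
        if len(self.sample_ids) != m:
            raise ValueError(
                f"view {self.name!r}: {len(self.sample_ids)} sample IDs "
                f"for {m} columns"
            )
        for kind, ids in (("feature", self.feature_ids),
                          ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"view {self.name!r}: duplicate {kind} IDs")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiViewSet:
    """An ordered collection of views sharing samples (Case I) or features
    (Case II)."""

    views: Sequence[ViewMatrix]
    case: Literal["shared_samples", "shared_features"] = CASE_SHARED_SAMPLES

    def __post_init__(self) -> None:
        if self.case not in (CASE_SHARED_SAMPLES, CASE_SHARED_FEATURES):
            raise ValueError(f"unknown case {self.case!r}")
        if len(self.views) < 2:
            raise ValueError("need at least two views")
        names = [v.name for v in self.views]
        if len(set(names)) != len(names):
            raise ValueError("view names must be unique")
        ref = self.views[0]
        for v in self.views[1:]:
            if self.case == CASE_SHARED_SAMPLES:
                if list(v.sample_ids) != list(ref.sample_ids):
                    raise ValueError(
                        f"Case I requires identical sample IDs across views; "
                        f"{v.name!r} differs from {ref.name!r}"
                    )
            else:
                if list(v.feature_ids) != list(ref.feature_ids):
                    raise ValueError(
                        f"Case II requires identical feature IDs across "
                        f"views; {v.name!r} differs from {ref.name!r}"
                    )

    @property
    def shared_ids(self) -> list[str]:
        if self.case == CASE_SHARED_SAMPLES:
            return list(self.views[0].sample_ids)
        return list(self.views[0].feature_ids)

    @property
    def m(self) -> int:
        return len(self.views)


@dataclass
class MultiwayArray:
    """A dense product tensor with labelled modes.

    Type I has m+1 modes (one per view plus the shared mode, last);
    Type II has m modes (one per view).
    """

    values: np.ndarray
    mode_labels: Sequence[str]
    tensor_type: Literal["type1", "type2"]
    case: str
    mode_ids: Sequence[Sequence[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.mode_labels) != self.values.ndim:
            raise ValueError("one mode label required per tensor mode")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def standardize(X: ViewMatrix) -> ViewMatrix:
    """Standardize each sample column to zero mean and sum of squares N.

    After the transform every column j satisfies ``sum_i x_ij = 0`` and
    ``sum_i x_ij**2 = N`` (the number of features), the normalisation used
    throughout for expression profiles.  Idempotent.
    """
    vals = X.values
    n = vals.shape[0]
    if n < 2:
        raise DegenerateColumnError(
            f"view {X.name!r}: need at least 2 features to standardize"
        )
    centered = vals - vals.mean(axis=0, keepdims=True)
    ss = (centered**2).sum(axis=0)
    bad = np.flatnonzero(ss == 0)
    if bad.size:
        raise DegenerateColumnError(
            f"view {X.name!r}: constant column(s) "
            f"{[X.sample_ids[i] for i in bad]} cannot be standardized"
        )
    out = centered * np.sqrt(n / ss)
    return replace(X, values=out)


def _view_axes(mset: MultiViewSet) -> tuple[list[np.ndarray], int]:
    """Per-view matrices oriented (own-axis, shared-axis) and shared size."""
    mats = []
    for v in mset.views:
        if mset.case == CASE_SHARED_SAMPLES:
            mats.append(v.values)  # (features, shared samples)
        else:
            mats.append(v.values.T)  # (samples, shared features)
    shared = mats[0].shape[1]
    return mats, shared


def _mode_metadata(mset: MultiViewSet, tensor_type: str):
    labels = [v.name for v in mset.views]
    if mset.case == CASE_SHARED_SAMPLES:
        ids = [list(v.feature_ids) for v in mset.views]
        shared_label, shared_ids = "sample", mset.shared_ids
    else:
        ids = [list(v.sample_ids) for v in mset.views]
        shared_label, shared_ids = "feature", mset.shared_ids
    if tensor_type == "type1":
        labels = labels + [shared_label]
        ids = ids + [shared_ids]
    return labels, ids


def build_type1(
    mset: MultiViewSet, element_cap: int = DEFAULT_ELEMENT_CAP
) -> MultiwayArray:
    """Dense (m+1)-mode Type I product tensor.

    Case I:  values[i1,...,im,j] = prod_k X_k[i_k, j].
    Case II: values[j1,...,jm,i] = prod_k X_k[i, j_k].
    Modes are ordered views-first, shared mode last.
    """
    mats, shared = _view_axes(mset)
    n_elem = int(np.prod([m.shape[0] for m in mats], dtype=np.int64)) * shared
    if n_elem > element_cap:
        raise ElementCapError(
            f"Type I tensor would hold {n_elem:,} elements "
            f"(cap {element_cap:,}); memory and time grow like M*prod(N_k) — "
            f"use a Type II tensor instead"
        )
    letters = string.ascii_lowercase
    subs = ",".join(f"{letters[k]}z" for k in range(len(mats)))
    out = "".join(letters[: len(mats)]) + "z"
    values = np.einsum(f"{subs}->{out}", *mats)
    labels, ids = _mode_metadata(mset, "type1")
    return MultiwayArray(values, labels, "type1", mset.case, ids)


def build_type2(mset: MultiViewSet) -> MultiwayArray:
    """m-mode Type II tensor: Type I summed over the shared mode.

    Computed by direct contraction without materializing the Type I tensor;
    for two Case I views this is the matrix product ``X1 @ X2.T``.
    """
    mats, _ = _view_axes(mset)
    letters = string.ascii_lowercase
    subs = ",".join(f"{letters[k]}z" for k in range(len(mats)))
    out = "".join(letters[: len(mats)])
    values = np.einsum(f"{subs}->{out}", *mats, optimize=True)
    labels, ids = _mode_metadata(mset, "type2")
    return MultiwayArray(values, labels, "type2", mset.case, ids)
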