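"""TSV readers/writers for view matrices, labels, and decomposition outputs.

Matrix format: tab-separated, header row of sample IDs, first column of
feature IDs.  All component indices in written tables are 1-based; identity
is carried by IDs, never by position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ClassLabels
from .hosvd import CoreRanking, HOSVDResult, ProjectedVectors
from .selection import SelectionResult
from .tensors import ViewMatrix

__all__ = [
    "read_view_matrix",
    "write_view_matrix",
    "read_class_labels",
    "write_factors",
    "write_core_ranking",
    "write_projected",
    "write_selection",
    "write_manifest",
]


class ParseError(ValueError):
    pass


def read_view_matrix(path: str | Path, name: str | None = None) -> ViewMatrix:
    """Read a features x samples TSV (header = sample IDs, col 0 = feature IDs)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}, line 1: expected >= 2 tab-separated columns")
        sample_ids = header[1:]
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}, line {lineno}: {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            feature_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-numeric cell "
                                 f"({exc})") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    try:
        return ViewMatrix(np.array(rows), feature_ids, sample_ids,
                          name=name or path.stem)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_view_matrix(X: ViewMatrix, path: str | Path) -> None:
    df = pd.DataFrame(X.values, index=X.feature_ids, columns=X.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_class_labels(path: str | Path) -> ClassLabels:
    """Labels TSV: columns sample_id, class[, time]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "class"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    return ClassLabels(list(df["sample_id"]), list(df["class"]))


def write_factors(res: HOSVDResult, out_dir: str | Path) -> list[Path]:
    """One TSV per mode: rows = mode indices/IDs, columns = component 1..R."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, (label, U) in enumerate(zip(res.mode_labels, res.factors)):
        ids = (list(res.mode_ids[k]) if res.mode_ids
               else [str(i + 1) for i in range(U.shape[0])])
        df = pd.DataFrame(
            U, index=ids,
            columns=[f"component_{l}" for l in range(1, U.shape[1] + 1)],
        )
        df.index.name = "id"
        p = out_dir / f"factors_{label}.tsv"
        df.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def write_core_ranking(ranking: CoreRanking, path: str | Path,
                       mode_labels: list[str] | None = None) -> None:
    """Long-format TSV: one row per core entry, sorted by decreasing |G|."""
    if not ranking.entries:
        raise ValueError("empty core ranking")
    m = len(ranking.entries[0][0])
    cols = (mode_labels if mode_labels is not None
            else [f"l{k + 1}" for k in range(m)])
    rows = [list(idx) + [val] for idx, val in ranking.entries]
    pd.DataFrame(rows, columns=cols + ["G"]).to_csv(path, sep="\t",
                                                    index=False)


def write_projected(proj: ProjectedVectors, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mat in proj.vectors.items():
        df = pd.DataFrame(
            mat.T, index=proj.shared_ids,
            columns=[f"component_{l}" for l in range(1, mat.shape[0] + 1)],
        )
        df.index.name = "id"
        p = out_dir / f"projected_{name}.tsv"
        df.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def write_selection(sel: SelectionResult, path: str | Path) -> None:
    sel.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
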