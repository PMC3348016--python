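"""Delimited-text I/O for feature tables, pairwise matrices and reports.

All files are headered TSV; protein ids are the join key everywhere.
Feature tables have columns ``id``, optional ``label``, then numeric
features.  Matrix files carry one metadata comment line
(``# mode=... has_query=...``) followed by an id-indexed square table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .measures import FeatureTable, PairwiseMatrix

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_report",
    "write_curve_tsv",
]

PathLike = Union[str, Path]


def write_feature_table(table: FeatureTable, path: PathLike) -> None:
    data: dict = {"id": table.ids}
    if table.labels is not None:
        data["label"] = ["" if l is None else l for l in table.labels]
    for m in range(table.dim):
        data[f"f{m}"] = table.X[:, m]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_feature_table(path: PathLike) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"feature table {path} lacks an 'id' column")
    labels = None
    if "label" in df.columns:
        raw = df["label"].tolist()
        labels = [None if (isinstance(l, float) and np.isnan(l)) or l == "" else str(l) for l in raw]
    feat_cols = [c for c in df.columns if c not in ("id", "label")]
    if not feat_cols:
        raise ValueError(f"feature table {path} has no feature columns")
    X = df[feat_cols].to_numpy(dtype=float)
    return FeatureTable(ids=df["id"].tolist(), X=X, labels=labels)


def write_matrix(matrix: PairwiseMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode={matrix.mode}\thas_query={str(matrix.has_query).lower()}\n")
        pd.DataFrame(matrix.M, index=matrix.ids, columns=matrix.ids).to_csv(fh, sep="\t")


def read_matrix(path: PathLike) -> PairwiseMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(
                f"matrix file {path} lacks the '# mode=...' metadata line"
            )
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
        )
        df = pd.read_csv(fh, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"matrix file {path}: row and column ids differ")
    return PairwiseMatrix(
        df.to_numpy(dtype=float),
        meta.get("mode", "dissimilarity"),  # type: ignore[arg-type]
        ids,
        has_query=meta.get("has_query", "false") == "true",
    )


def read_labels(path: PathLike) -> dict[str, str]:
    """Read an id -> label mapping from a TSV with 'id' and 'label' columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"label file {path} needs 'id' and 'label' columns")
    return dict(zip(df["id"], df["label"]))


def write_report(report: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_curve_tsv(rows: list[dict], path: PathLike) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
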