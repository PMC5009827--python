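"""Readers and writers for the delimited-text formats the tool touches.

Matrix files: first row = feature names, first column = sample IDs, tab- or
comma-delimited (sniffed from the header line); output is always
tab-delimited with 17-significant-digit floats so write->read round trips are
lossless at double precision.

Edge-list files: two tab-separated feature *names* per line, ``#`` comments
allowed; an absent file means the complete graph (group-pursuit mode).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, is_dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .penalty_graph import FeatureGraph
from .solver import PairedData

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_paired_matrices",
    "write_paired_matrices",
    "read_edge_list",
    "write_edge_list",
    "read_loadings",
    "write_loadings",
    "file_digest",
    "write_metadata",
]

_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(path: str) -> pd.DataFrame:
    """Read a labelled numeric matrix; locate the first bad cell on failure."""
    if not os.path.exists(path):
        raise ValidationError(f"matrix file not found: {path}")
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as err:  # malformed structure
        raise ParseError(f"cannot parse {path}: {err}") from err
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample ID {dup!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            row = bad_rows[0] if len(bad_rows) else df.index[df[col].isna()][0]
            raise ParseError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValidationError(
            f"missing value in {path} at row {row!r}, column {col!r}; "
            "complete cases are required"
        )
    return df


def write_matrix(
    path: str,
    M: np.ndarray,
    sample_ids: Sequence[str],
    feature_names: Sequence[str],
) -> None:
    df = pd.DataFrame(np.asarray(M, dtype=float), index=list(sample_ids),
                      columns=list(feature_names))
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_paired_matrices(x_path: str, y_path: str) -> PairedData:
    """Read X and Y and inner-join them on sample IDs (X's input order kept)."""
    dx = read_matrix(x_path)
    dy = read_matrix(y_path)
    y_index = set(dy.index)
    common = [s for s in dx.index if s in y_index]
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} overlapping sample IDs between "
            f"{x_path} and {y_path}; need at least 3"
        )
    dx = dx.loc[common]
    dy = dy.loc[common]
    return PairedData(
        X=dx.to_numpy(),
        Y=dy.to_numpy(),
        sample_ids=common,
        x_features=list(dx.columns),
        y_features=list(dy.columns),
    )


def write_paired_matrices(x_path: str, y_path: str, data: PairedData) -> None:
    write_matrix(x_path, data.X, data.sample_ids, data.x_features)
    write_matrix(y_path, data.Y, data.sample_ids, data.y_features)


def read_edge_list(path: str | None, feature_names: Sequence[str]) -> FeatureGraph:
    """Edge list by feature name; absent path yields the complete graph."""
    names = [str(x) for x in feature_names]
    if path is None or not os.path.exists(path):
        return FeatureGraph.complete(len(names))
    index = {name: i for i, name in enumerate(names)}
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two feature names, got {line!r}"
                )
            a, b = (s.strip() for s in parts)
            for name in (a, b):
                if name not in index:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown feature name {name!r}"
                    )
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
            pairs.append((index[a], index[b]))
    return FeatureGraph.from_pairs(len(names), pairs)


def write_edge_list(path: str, graph: FeatureGraph, feature_names: Sequence[str]) -> None:
    names = [str(x) for x in feature_names]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# feature_a\tfeature_b\n")
        for i, j in graph.edges:
            fh.write(f"{names[i]}\t{names[j]}\n")


def write_loadings(path: str, feature_names: Sequence[str], values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float).ravel()
    if len(feature_names) != values.shape[0]:
        raise ValidationError("feature name count does not match loading length")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\tweight\n")
        for name, val in zip(feature_names, values):
            fh.write(f"{name}\t{_FLOAT_FMT % val}\n")


def read_loadings(path: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != ["feature", "weight"]:
        raise ParseError(f"{path}: expected columns 'feature', 'weight'")
    return [str(x) for x in df["feature"]], df["weight"].to_numpy(dtype=float)


def file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_metadata(path: str, record: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(record), fh, indent=2, default=str)
        fh.write("\n")
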