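"""Readers and writers for the plain-text formats the pipeline touches.

Matrices are tab-separated with a header row of sample ids and feature ids
in the first column (the layout of a GEO series matrix after probe
collapsing).  Sample labels live in a separate two-column TSV
``sample_id<TAB>class`` so the matrices stay platform-agnostic.  Gene sets
use GMT-style lines: term id, member count (or free-text description),
then the members.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    NORMAL,
    TUMOR,
    AnnotationMap,
    OmicsMatrix,
    TargetPredictionTable,
    ValidationError,
)


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (sample_id, class) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: label file must have exactly two columns")
    labels: dict[str, str] = {}
    for sample, cls in df.itertuples(index=False):
        if sample in labels:
            raise ValidationError(f"{path}: duplicate sample id {sample!r}")
        if cls not in (TUMOR, NORMAL):
            raise ValidationError(
                f"{path}: sample {sample!r} has class {cls!r}; expected 'tumor' or 'normal'"
            )
        labels[sample] = cls
    return labels


def read_matrix(path: str | os.PathLike, level: str, labels_path: str | os.PathLike) -> OmicsMatrix:
    """Read a feature-by-sample TSV plus its label file into an OmicsMatrix.

    Row and column order are preserved from the file.  Duplicate ids,
    unlabeled samples, missing or non-numeric cells raise a
    :class:`ValidationError` naming the file, row and column involved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    labels = read_labels(labels_path)
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValidationError(f"{labels_path}: no label for sample {missing[0]!r}")
    return OmicsMatrix(
        level=level,
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        values=numeric.to_numpy(dtype=float),
        labels=[labels[s] for s in df.columns],
    )


def write_matrix(matrix: OmicsMatrix, path: str | os.PathLike, labels_path: str | os.PathLike) -> None:
    """Write a matrix TSV and its companion label TSV."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")
    with open(labels_path, "w") as fh:
        for s, lab in zip(matrix.sample_ids, matrix.labels):
            fh.write(f"{s}\t{lab}\n")


def read_gmt(path: str | os.PathLike) -> AnnotationMap:
    """Parse a GMT-style gene-set file.

    Each line: term id, a member-count or free-text description, then the
    member ids, tab-separated.  When the second field is an integer it must
    equal the member count.
    """
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected term, size/description and >=1 member"
                )
            term, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: term {term!r} lists no members")
            if term in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term!r}")
            if desc.isdigit() and int(desc) != len(members):
                raise ValidationError(
                    f"{path}:{lineno}: term {term!r} declares {desc} members but lists {len(members)}"
                )
            terms[term] = frozenset(members)
            descriptions[term] = desc
    return AnnotationMap(terms=terms, descriptions=descriptions)


def write_gmt(annotation: AnnotationMap, path: str | os.PathLike) -> None:
    """Write an AnnotationMap as GMT lines (member count in the second field)."""
    with open(path, "w") as fh:
        for term, members in annotation.terms.items():
            ordered = sorted(members)
            fh.write("\t".join([term, str(len(ordered)), *ordered]) + "\n")


def read_predictions(path: str | os.PathLike, tool_universe: set[str] | None = None) -> TargetPredictionTable:
    """Read a (microRNA, gene, tool) TSV with header into a TargetPredictionTable.

    When `tool_universe` is None the observed tool names define it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    universe = frozenset(tool_universe) if tool_universe is not None else frozenset(df["tool"]) if "tool" in df else frozenset()
    return TargetPredictionTable(frame=df, tool_universe=universe)


def write_predictions(table: TargetPredictionTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any tabular result as TSV with header; rejects empty tables."""
    if table is None or len(table) == 0:
        raise ValidationError(f"refusing to write empty table to {path}")
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | os.PathLike) -> frozenset[str]:
    """Read a reference gene list: either one id per line or a single GMT line."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) == 1 and "\t" in lines[0]:
        fields = lines[0].split("\t")
        return frozenset(m for m in fields[2:] if m)
    return frozenset(ln.strip() for ln in lines)
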