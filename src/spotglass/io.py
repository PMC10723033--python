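"""Readers and writers bridging standard file formats to point tables.

Supported: delimited point tables (CSV/TSV with a header), 10x Visium
``tissue_positions`` CSVs in both on-disk dialects (the headerless
Space Ranger <2.0 ``tissue_positions_list.csv`` and the headered
``tissue_positions.csv``), and Matrix Market expression triplets with
sidecar barcode/feature TSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import (
    CATEGORICAL,
    CONTINUOUS,
    AnnotationColumn,
    PointTable,
    ValidationError,
    infer_kind,
    validate_table,
)

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "read_visium_positions",
    "read_mtx_expression",
    "attach_annotation",
]

VISIUM_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_points_csv(
    path: str | Path,
    x_col: str = "x",
    y_col: str = "y",
    id_col: str = "id",
    kind_overrides: Mapping[str, str] | None = None,
    coord_mode: str = "cartesian",
    sep: str | None = None,
) -> PointTable:
    """Read a delimited point table.

    Every column other than the id and coordinate columns becomes an
    annotation, with kind inferred from its values (numeric → continuous,
    strings → categorical) unless named in ``kind_overrides``.  Empty
    cells become missing values.
    """
    path = Path(path)
    kind_overrides = dict(kind_overrides or {})
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=object, keep_default_na=False)
    for col in (id_col, x_col, y_col):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not in {path.name}; available: {list(df.columns)}"
            )
    ids = df[id_col].astype(str).to_numpy()

    def parse_coord(name):
        out = np.empty(len(df), dtype=float)
        for i, v in enumerate(df[name]):
            try:
                out[i] = float(v)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"unparsable {name} coordinate {v!r} at data row {i + 1}"
                ) from None
        return out

    x = parse_coord(x_col)
    y = parse_coord(y_col)
    table = PointTable(point_ids=ids, x=x, y=y, coord_mode=coord_mode)
    for name in df.columns:
        if name in (id_col, x_col, y_col):
            continue
        raw = []
        for v in df[name]:
            if v == "" or v is None:
                raw.append(None)
                continue
            ov = kind_overrides.get(name)
            if ov == CATEGORICAL:
                raw.append(str(v))
                continue
            try:
                raw.append(float(v))
            except (TypeError, ValueError):
                raw.append(str(v))
        col = AnnotationColumn.from_raw(name, raw, kind=kind_overrides.get(name))
        table = table.with_annotation(col)
    return validate_table(table)


def write_points_csv(table: PointTable, path: str | Path, sep: str | None = None) -> Path:
    """Write a point table; round-trips through :func:`read_points_csv`.

    Reals are written with ``repr`` precision so numeric values survive
    the trip to at least 1e-12 relative.
    """
    path = Path(path)
    data: dict[str, list] = {
        "id": [str(i) for i in table.point_ids],
        "x": [repr(float(v)) for v in table.x],
        "y": [repr(float(v)) for v in table.y],
    }
    for name, col in table.annotations.items():
        if col.kind == CONTINUOUS:
            data[name] = [
                "" if m else repr(float(v)) for v, m in zip(col.values, col.missing)
            ]
        else:
            data[name] = ["" if m else str(v) for v, m in zip(col.values, col.missing)]
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path, sep), index=False)
    return path


def _visium_has_header(path: Path) -> bool:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "barcode" in first.split(",")[0]


def read_visium_positions(
    path: str | Path, drop_out_of_tissue: bool = False
) -> PointTable:
    """Read a 10x Visium tissue-positions CSV into an image-mode table.

    x is taken from ``pxl_col_in_fullres`` and y from
    ``pxl_row_in_fullres`` (full-resolution image pixels, y down).
    ``in_tissue``, ``array_row`` and ``array_col`` are kept verbatim as
    annotations; rows with ``in_tissue == 0`` are dropped when
    ``drop_out_of_tissue`` is set.  Both the headered and headerless
    dialects are accepted and yield identical tables.
    """
    path = Path(path)
    header = 0 if _visium_has_header(path) else None
    df = pd.read_csv(path, header=header, dtype=object)
    if df.shape[1] != 6:
        raise FormatError(
            f"{path.name}: expected 6 columns "
            f"({', '.join(VISIUM_COLUMNS)}), found {df.shape[1]}"
        )
    df.columns = VISIUM_COLUMNS
    in_tissue = df["in_tissue"].astype(int)
    if not in_tissue.isin([0, 1]).all():
        raise FormatError(f"{path.name}: in_tissue must be 0/1")
    if drop_out_of_tissue:
        df = df[in_tissue == 1].reset_index(drop=True)
        in_tissue = in_tissue[in_tissue == 1].reset_index(drop=True)
    table = PointTable(
        point_ids=df["barcode"].astype(str).to_numpy(),
        x=df["pxl_col_in_fullres"].astype(float).to_numpy(),
        y=df["pxl_row_in_fullres"].astype(float).to_numpy(),
        coord_mode="image",
    )
    table = table.with_annotation(
        AnnotationColumn.from_raw(
            "in_tissue", [str(v) for v in in_tissue], kind=CATEGORICAL
        )
    )
    for name in ("array_row", "array_col"):
        table = table.with_annotation(
            AnnotationColumn.from_raw(name, df[name].astype(float).tolist())
        )
    return validate_table(table)


def read_mtx_expression(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    feature_name: str,
) -> dict[str, float]:
    """Extract one feature's expression from an MTX triplet as a
    barcode → value map.

    The matrix is features × barcodes (10x convention).  Entries absent
    from the sparse file are 0, following sparse count semantics, not
    missing.  Feature lookup matches either the feature id (column 1) or
    gene symbol (column 2) of ``features.tsv``.
    """
    def read_lines(p):
        with open(p) as fh:
            return [ln.rstrip("\n") for ln in fh if ln.strip() != ""]

    barcodes = [ln.split("\t")[0] for ln in read_lines(barcodes_path)]
    feature_rows = [ln.split("\t") for ln in read_lines(features_path)]
    mat = scipy.io.mmread(str(matrix_path)).tocsr()
    if mat.shape[0] != len(feature_rows):
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but features file lists "
            f"{len(feature_rows)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but barcodes file lists "
            f"{len(barcodes)}"
        )
    row_idx = None
    for i, fields in enumerate(feature_rows):
        if feature_name in fields[:2]:
            row_idx = i
            break
    if row_idx is None:
        raise KeyError(f"feature {feature_name!r} not found in features file")
    vals = np.asarray(mat.getrow(row_idx).todense()).ravel()
    return {bc: float(v) for bc, v in zip(barcodes, vals)}


def attach_annotation(
    table: PointTable,
    mapping: Mapping[str, float | str],
    name: str,
    kind: str | None = None,
) -> PointTable:
    """Join a per-id value map onto a table as a new annotation column.

    Ids absent from the mapping become missing values.
    """
    if name in table.annotations:
        raise ValidationError(f"annotation {name!r} already present")
    raw = [mapping.get(str(pid)) for pid in table.point_ids]
    col = AnnotationColumn.from_raw(name, raw, kind=kind)
    return table.with_annotation(col)
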