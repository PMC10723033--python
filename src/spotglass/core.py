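"""Validated point-table data model shared by plotting and binning.

A :class:`PointTable` is a set of uniquely identified points in a 2D
coordinate system (tissue pixels, micrometres, or embedding units)
carrying named annotation columns.  Each :class:`AnnotationColumn` is
either *continuous* (real-valued, e.g. gene expression) or
*categorical* (finite label set, e.g. spatial domain or cell type).
Coordinates are never missing; annotation values may be, and missing
entries are tracked with an explicit boolean mask rather than NaN
sentinels so that categorical columns stay clean strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AnnotationColumn",
    "PointTable",
    "ValidationError",
    "infer_kind",
    "validate_table",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: fill used wherever a point's annotation value is missing
NEUTRAL_GREY = "#bdbdbd"


class ValidationError(ValueError):
    """A point table or annotation column violates a structural invariant."""


def infer_kind(values: Sequence, override: str | None = None) -> str:
    """Classify a raw value sequence as ``continuous`` or ``categorical``.

    Numeric input (ints, floats, numpy numbers) is continuous; strings and
    booleans are categorical.  ``override`` always wins when given.
    Integer-valued columns default to continuous (expression counts are
    integers); pass ``override="categorical"`` to treat integer cluster
    ids as labels.

    Raises
    ------
    ValidationError
        On an empty sequence, a mix of numeric and string values without
        an override, or an unknown override.
    """
    if override is not None:
        if override not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(f"unknown kind override: {override!r}")
        return override
    vals = list(values)
    if not vals:
        raise ValidationError("cannot infer kind of an empty sequence")
    def is_num(v):
        return isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool)
    def is_lab(v):
        return isinstance(v, (str, bool, np.bool_, np.str_))
    present = [v for v in vals if v is not None]
    if present and all(is_num(v) for v in present):
        return CONTINUOUS
    if present and all(is_lab(v) for v in present):
        return CATEGORICAL
    raise ValidationError(
        "mixed numeric/string values; pass an explicit kind override"
    )


@dataclass(frozen=True)
class AnnotationColumn:
    """One named per-point variable, continuous or categorical."""

    name: str
    kind: str
    values: np.ndarray
    missing: np.ndarray  # boolean mask aligned to values

    @classmethod
    def from_raw(
        cls,
        name: str,
        values: Sequence,
        kind: str | None = None,
    ) -> "AnnotationColumn":
        """Build a column from raw Python/numpy values.

        ``None`` and NaN entries become missing.  Kind is inferred from
        the non-missing values unless given explicitly.
        """
        raw = list(values)
        missing = np.array(
            [v is None or (isinstance(v, float) and np.isnan(v)) for v in raw],
            dtype=bool,
        )
        present = [v for v, m in zip(raw, missing) if not m]
        k = infer_kind(present if present else raw, override=kind)
        if k == CONTINUOUS:
            arr = np.array(
                [np.nan if m else float(v) for v, m in zip(raw, missing)],
                dtype=float,
            )
        else:
            arr = np.array(
                ["" if m else str(v) for v, m in zip(raw, missing)],
                dtype=object,
            )
        return cls(name=name, kind=k, values=arr, missing=missing)

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if len(self.values) != len(self.missing):
            raise ValidationError(
                f"column {self.name!r}: values/missing length mismatch"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def levels(self) -> list[str]:
        """Sorted distinct labels among non-missing values (categorical only)."""
        if self.kind != CATEGORICAL:
            raise ValidationError(f"column {self.name!r} is not categorical")
        return sorted({str(v) for v, m in zip(self.values, self.missing) if not m})

    def check(self, n_points: int) -> None:
        """Raise unless this column satisfies its invariants for a table of
        ``n_points`` points."""
        if len(self) != n_points:
            raise ValidationError(
                f"column {self.name!r} has {len(self)} values for {n_points} points"
            )
        if self.kind == CONTINUOUS:
            vals = np.asarray(self.values, dtype=float)
            bad = ~np.isfinite(vals) & ~self.missing
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"column {self.name!r}: non-finite value at position {i} "
                    "outside the missing mask"
                )
        else:
            if not self.levels and not self.missing.all():
                raise ValidationError(f"column {self.name!r}: empty level set")


@dataclass(frozen=True)
class PointTable:
    """Points in a 2D coordinate system with named annotation columns.

    ``coord_mode="image"`` means the y axis increases downward (full-
    resolution microscopy pixels); rendering flips the axis, stored
    coordinates are never mutated.  ``"cartesian"`` is the convention
    for embeddings (UMAP, t-SNE, PCA).
    """

    point_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    coord_mode: str = "cartesian"
    annotations: Mapping[str, AnnotationColumn] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "point_ids", np.asarray(self.point_ids, dtype=object))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "annotations", dict(self.annotations))

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    def annotation(self, name: str) -> AnnotationColumn:
        """Look up a column by name; unknown names fail loudly."""
        try:
            return self.annotations[name]
        except KeyError:
            avail = ", ".join(sorted(self.annotations)) or "<none>"
            raise KeyError(
                f"no annotation named {name!r}; available: {avail}"
            ) from None

    def with_annotation(self, column: AnnotationColumn) -> "PointTable":
        """Return a new table with ``column`` added; duplicate names error."""
        if column.name in self.annotations:
            raise ValidationError(f"annotation {column.name!r} already present")
        column.check(self.n_points)
        ann = dict(self.annotations)
        ann[column.name] = column
        return replace(self, annotations=ann)

    def without_annotation(self, name: str) -> "PointTable":
        ann = dict(self.annotations)
        ann.pop(name, None)
        return replace(self, annotations=ann)


def validate_table(table: PointTable) -> PointTable:
    """Check every structural invariant and return the table unchanged.

    Raises :class:`ValidationError` naming the first duplicate id, the
    first misaligned column, or the first point with a non-finite
    coordinate.
    """
    if table.coord_mode not in ("cartesian", "image"):
        raise ValidationError(f"unknown coord_mode {table.coord_mode!r}")
    ids = [str(i) for i in table.point_ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate point id {i!r}")
        seen.add(i)
    n = table.n_points
    if len(table.x) != n or len(table.y) != n:
        raise ValidationError(
            f"coordinate arrays misaligned: {len(table.x)}/{len(table.y)} for {n} ids"
        )
    for axis, arr in (("x", table.x), ("y", table.y)):
        bad = ~np.isfinite(arr)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-finite {axis} coordinate for point {ids[i]!r}"
            )
    for name, col in table.annotations.items():
        if col.name != name:
            raise ValidationError(
                f"annotation registered as {name!r} but named {col.name!r}"
            )
        col.check(n)
    return table
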