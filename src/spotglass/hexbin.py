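"""Hexagonal binning of 2D embeddings with majority-label regions.

Scatter plots of large embeddings (UMAP, t-SNE) overplot badly, and
annotating clusters with convex hulls produces overlapping regions whose
membership is ambiguous.  The strategy here: partition the plane into
pointy-top hexagons, summarize each occupied cell (point count, mean of
each continuous variable, majority label of each categorical variable),
and outline each label's territory with the hexagon edges that separate
it from other labels or empty space.  Unlike hulls, these regions
partition the occupied cells, so region interiors can never overlap.

Hexagons are addressed with axial coordinates ``(q, r)``; cell centers
sit at ``(x0 + s*sqrt(3)*(q + r/2), y0 + s*1.5*r)`` for circumradius
``s``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core import CATEGORICAL, CONTINUOUS, PointTable, ValidationError

__all__ = [
    "HexGrid",
    "CellStats",
    "HexAggregate",
    "RegionBoundary",
    "build_grid",
    "assign_hex",
    "aggregate",
    "extract_label_boundaries",
    "hex_cell_vertices",
]

SQRT3 = math.sqrt(3.0)

#: unit-circumradius pointy-top vertex angles, degrees (top vertex at 90)
_VERTEX_ANGLES = (-30.0, 30.0, 90.0, 150.0, 210.0, 270.0)

#: axial neighbor directions paired with the vertex indices of the shared
#: edge (edge i spans vertices _EDGE_VERTICES[i]); order matches
#: _NEIGHBOR_DIRS so direction k lies across edge k
_NEIGHBOR_DIRS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))
_EDGE_VERTICES = ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0))

_UNIT_VERTICES = tuple(
    (math.cos(math.radians(a)), math.sin(math.radians(a))) for a in _VERTEX_ANGLES
)


@dataclass(frozen=True)
class HexGrid:
    """Pointy-top hexagonal lattice: circumradius ``size``, origin at the
    center of cell (0, 0)."""

    size: float
    origin: tuple[float, float]
    nbins: int

    def __post_init__(self):
        if not self.size > 0:
            raise ValidationError(f"hexagon size must be positive, got {self.size}")
        if self.nbins < 1:
            raise ValidationError(f"nbins must be >= 1, got {self.nbins}")

    def center(self, q: int, r: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + self.size * SQRT3 * (q + r / 2.0), y0 + self.size * 1.5 * r)


def build_grid(
    x_extent: tuple[float, float],
    y_extent: tuple[float, float],
    nbins: int,
) -> HexGrid:
    """Build a grid whose hexagon width tiles ``nbins`` columns across the
    x extent: ``size = x_range / (nbins * sqrt(3))`` (hexagon width is
    ``size*sqrt(3)`` for pointy-top).  The origin is the extent's
    lower-left corner, so that corner lies in cell (0, 0)'s column."""
    (x_min, x_max), (y_min, y_max) = x_extent, y_extent
    if not (x_max > x_min and y_max > y_min):
        raise ValidationError(
            f"degenerate extent: x={x_extent}, y={y_extent} (max must exceed min)"
        )
    if nbins < 1:
        raise ValidationError(f"nbins must be >= 1, got {nbins}")
    size = (x_max - x_min) / (nbins * SQRT3)
    return HexGrid(size=size, origin=(x_min, y_min), nbins=nbins)


def hex_cell_vertices(grid: HexGrid, q: int, r: int) -> list[tuple[float, float]]:
    """The six vertices of a cell, in angular order, quantized so shared
    vertices of adjacent cells compare equal."""
    cx, cy = grid.center(q, r)
    s = grid.size
    out = []
    for ux, uy in _UNIT_VERTICES:
        # quantize in units of size: stable to float noise across neighbors
        vx = round((cx + s * ux) / s, 6) * s
        vy = round((cy + s * uy) / s, 6) * s
        out.append((vx, vy))
    return out


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cube rounding of fractional axial coordinates."""
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(int), r.astype(int)


def assign_hex(points: PointTable, grid: HexGrid) -> np.ndarray:
    """Assign each point to the cell whose center is nearest (Euclidean).

    Fractional axial coordinates plus cube rounding find the candidate;
    exact equidistance (edge/vertex points) resolves to the
    lexicographically smallest ``(q, r)`` among the tied cells, so the
    result is independent of input row order.  Returns an ``(n, 2)``
    integer array of ``(q, r)`` pairs.
    """
    x0, y0 = grid.origin
    s = grid.size
    dx = (points.x - x0) / s
    dy = (points.y - y0) / s
    qf = SQRT3 / 3.0 * dx - dy / 3.0
    rf = 2.0 / 3.0 * dy
    q, r = _axial_round(qf, rf)

    # tie resolution: compare against the rounded cell and its 6 neighbors
    cand = np.empty((len(q), 7, 2), dtype=int)
    cand[:, 0, 0], cand[:, 0, 1] = q, r
    for k, (dq, dr) in enumerate(_NEIGHBOR_DIRS, start=1):
        cand[:, k, 0], cand[:, k, 1] = q + dq, r + dr
    cq = cand[..., 0].astype(float)
    cr = cand[..., 1].astype(float)
    cx = x0 + s * SQRT3 * (cq + cr / 2.0)
    cy = y0 + s * 1.5 * cr
    d2 = (cx - points.x[:, None]) ** 2 + (cy - points.y[:, None]) ** 2
    eps = (s * 1e-9) ** 2
    out = np.empty((len(q), 2), dtype=int)
    dmin = d2.min(axis=1)
    for i in range(len(q)):
        tied = np.flatnonzero(d2[i] <= dmin[i] + eps)
        best = min((int(cand[i, j, 0]), int(cand[i, j, 1])) for j in tied)
        out[i] = best
    return out


@dataclass(frozen=True)
class CellStats:
    count: int
    means: Mapping[str, float]
    majority: Mapping[str, str]
    tally: Mapping[str, Mapping[str, int]]


@dataclass(frozen=True)
class HexAggregate:
    """Per-cell summaries over occupied cells only."""

    grid: HexGrid
    cells: Mapping[tuple[int, int], CellStats]
    continuous: tuple[str, ...]
    categorical: tuple[str, ...]

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.cells.values())


def _majority(tally: Counter) -> str:
    """Most frequent label; ties broken by lexicographically smallest."""
    top = max(tally.values())
    return min(lab for lab, n in tally.items() if n == top)


def aggregate(
    points: PointTable,
    grid: HexGrid,
    continuous: Iterable[str] = (),
    categorical: Iterable[str] = (),
) -> HexAggregate:
    """Bin points and summarize each occupied cell.

    Continuous variables get the arithmetic mean of non-missing member
    values (NaN if all missing); categorical variables get a full label
    tally and the majority label.
    """
    continuous = tuple(continuous)
    categorical = tuple(categorical)
    cont_cols = {}
    for name in continuous:
        col = points.annotation(name)
        if col.kind != CONTINUOUS:
            raise ValidationError(f"column {name!r} is not continuous")
        cont_cols[name] = col
    cat_cols = {}
    for name in categorical:
        col = points.annotation(name)
        if col.kind != CATEGORICAL:
            raise ValidationError(f"column {name!r} is not categorical")
        cat_cols[name] = col

    qr = assign_hex(points, grid)
    members: dict[tuple[int, int], list[int]] = {}
    for i, (q, r) in enumerate(map(tuple, qr)):
        members.setdefault((q, r), []).append(i)

    cells = {}
    for cell, idx in members.items():
        idx = np.asarray(idx)
        means = {}
        for name, col in cont_cols.items():
            vals = np.asarray(col.values, dtype=float)[idx]
            ok = ~col.missing[idx]
            means[name] = float(vals[ok].mean()) if ok.any() else float("nan")
        majority = {}
        tally = {}
        for name, col in cat_cols.items():
            labs = [
                str(col.values[i]) for i in idx if not col.missing[i]
            ]
            t = Counter(labs)
            tally[name] = dict(t)
            majority[name] = _majority(t) if t else ""
        cells[cell] = CellStats(
            count=len(idx), means=means, majority=majority, tally=tally
        )
    return HexAggregate(
        grid=grid, cells=cells, continuous=continuous, categorical=categorical
    )


Segment = tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class RegionBoundary:
    """Per-label sets of hexagon edge segments outlining label regions.

    An edge belongs to a label iff it borders an occupied cell of that
    majority and the cell across it is unoccupied or carries a different
    majority.  An edge between two occupied cells of *different*
    majorities therefore appears once in each label's set (two-sided
    convention); an edge interior to a same-label region appears in
    none, which is what guarantees regions never overlap.
    """

    segments: Mapping[str, frozenset[Segment]]

    @property
    def labels(self) -> list[str]:
        return sorted(self.segments)


def _oriented_segment(p1, p2) -> Segment:
    return (p1, p2) if p1 <= p2 else (p2, p1)


def extract_label_boundaries(
    agg: HexAggregate, grid: HexGrid, variable: str
) -> RegionBoundary:
    """Outline each majority-label region of ``variable`` with hexagon
    edges; see :class:`RegionBoundary` for the emission rule."""
    if variable not in agg.categorical:
        raise KeyError(
            f"variable {variable!r} was not aggregated as categorical; "
            f"have: {sorted(agg.categorical)}"
        )
    segsets: dict[str, set[Segment]] = {}
    for (q, r), stats in agg.cells.items():
        label = stats.majority.get(variable, "")
        verts = hex_cell_vertices(grid, q, r)
        for k, (dq, dr) in enumerate(_NEIGHBOR_DIRS):
            nb = (q + dq, r + dr)
            nb_stats = agg.cells.get(nb)
            if nb_stats is not None and nb_stats.majority.get(variable) == label:
                continue  # interior edge of a same-label region
            i, j = _EDGE_VERTICES[k]
            segsets.setdefault(label, set()).add(
                _oriented_segment(verts[i], verts[j])
            )
    return RegionBoundary(
        segments={lab: frozenset(s) for lab, s in segsets.items()}
    )
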