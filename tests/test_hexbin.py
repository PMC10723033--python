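"""Hex grid geometry, assignment, aggregation and boundary extraction,
each checked against an independent brute-force oracle."""

import math
from collections import Counter

import numpy as np
import pytest

from spotglass.core import AnnotationColumn, PointTable, ValidationError
from spotglass.hexbin import (
    CellStats,
    HexAggregate,
    HexGrid,
    aggregate,
    assign_hex,
    build_grid,
    extract_label_boundaries,
    hex_cell_vertices,
)

SQRT3 = math.sqrt(3.0)


# ---------------------------------------------------------------- oracles

def oracle_centers(grid, q_range, r_range):
    """All candidate cell centers by direct evaluation of the lattice rule."""
    x0, y0 = grid.origin
    out = {}
    for q in range(*q_range):
        for r in range(*r_range):
            out[(q, r)] = (
                x0 + grid.size * SQRT3 * (q + r / 2.0),
                y0 + grid.size * 1.5 * r,
            )
    return out


def oracle_assign(xs, ys, grid, q_range=(-40, 45), r_range=(-10, 45)):
    """Brute-force argmin over all candidate centers, lexicographic ties."""
    centers = oracle_centers(grid, q_range, r_range)
    cells = sorted(centers)  # lexicographic scan order resolves ties
    cx = np.array([centers[c][0] for c in cells])
    cy = np.array([centers[c][1] for c in cells])
    out = []
    for x, y in zip(xs, ys):
        d2 = (cx - x) ** 2 + (cy - y) ** 2
        dmin = d2.min()
        tied = np.flatnonzero(d2 <= dmin + (grid.size * 1e-9) ** 2)
        out.append(cells[tied[0]])
    return out


def oracle_vertices(grid, q, r):
    """Hexagon corners recomputed from first principles (angle formula)."""
    x0, y0 = grid.origin
    cx = x0 + grid.size * SQRT3 * (q + r / 2.0)
    cy = y0 + grid.size * 1.5 * r
    out = []
    for k in range(6):
        a = math.radians(-30 + 60 * k)
        out.append((cx + grid.size * math.cos(a), cy + grid.size * math.sin(a)))
    return out


def quantize(p, size):
    # 4 decimals: coarser than the implementation's internal rounding, so
    # double-rounding near half-way values cannot split a shared vertex
    return (round(p[0] / size, 4), round(p[1] / size, 4))


def canon_segments(segmap, size):
    """Quantized, orientation-normalized segment sets for comparison."""
    out = {}
    for lab, segs in segmap.items():
        out[lab] = {
            tuple(sorted((quantize(a, size), quantize(b, size))))
            for a, b in segs
        }
    return out


def oracle_boundaries(agg, grid, variable):
    """Per-edge classification: for every occupied cell and each of its 6
    edges, find the cell across the edge by reflecting the center through
    the edge midpoint, and emit the edge iff that cell is unoccupied or
    differently labeled."""
    occupied = {
        cell: stats.majority[variable] for cell, stats in agg.cells.items()
    }
    centers = {cell: grid.center(*cell) for cell in occupied}
    inv = {quantize(c, grid.size): cell for cell, c in centers.items()}
    segs = {}
    for cell, label in occupied.items():
        cx, cy = centers[cell]
        verts = oracle_vertices(grid, *cell)
        for k in range(6):
            a, b = verts[k], verts[(k + 1) % 6]
            mx, my = (a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0
            nb_center = (2 * mx - cx, 2 * my - cy)
            nb = inv.get(quantize(nb_center, grid.size))
            if nb is not None and occupied[nb] == label:
                continue
            segs.setdefault(label, set()).add(tuple(sorted((a, b))))
    return segs


def table_from_xy(xs, ys, **cols):
    t = PointTable(
        point_ids=[f"p{i}" for i in range(len(xs))], x=xs, y=ys
    )
    for name, (kind, values) in cols.items():
        t = t.with_annotation(AnnotationColumn.from_raw(name, values, kind=kind))
    return t


def make_aggregate(grid, majorities):
    """Hand-build an aggregate with given per-cell majority labels."""
    cells = {
        cell: CellStats(
            count=1, means={}, majority={"lab": lab}, tally={"lab": {lab: 1}}
        )
        for cell, lab in majorities.items()
    }
    return HexAggregate(
        grid=grid, cells=cells, continuous=(), categorical=("lab",)
    )


# ---------------------------------------------------------------- grid

def test_build_grid_size_follows_nbins_rule():
    g = build_grid((0, 10), (0, 10), nbins=10)
    assert g.size == pytest.approx(10 / (10 * SQRT3))
    assert g.origin == (0, 0)


@pytest.mark.parametrize("nbins", [0, -1])
def test_build_grid_rejects_bad_nbins(nbins):
    with pytest.raises(ValidationError):
        build_grid((0, 10), (0, 10), nbins=nbins)


def test_build_grid_rejects_degenerate_extent():
    with pytest.raises(ValidationError, match="degenerate"):
        build_grid((0, 0), (0, 1), nbins=5)


# ---------------------------------------------------------------- assign

def test_point_at_cell_center_maps_to_that_cell():
    g = build_grid((0, 10), (0, 10), nbins=8)
    cx, cy = g.center(2, 3)
    t = table_from_xy(np.array([cx]), np.array([cy]))
    assert assign_hex(t, g).tolist() == [[2, 3]]


def test_assignment_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    g = build_grid((0, 10), (0, 10), nbins=20)
    xs = rng.uniform(0, 10, 1000)
    ys = rng.uniform(0, 10, 1000)
    t = table_from_xy(xs, ys)
    got = [tuple(c) for c in assign_hex(t, g)]
    assert got == oracle_assign(xs, ys, g)


def test_edge_midpoint_tie_resolves_to_lexicographic_smaller():
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=1)
    # midpoint between centers of (0,0) and (1,0)
    mx = SQRT3 / 2.0
    t = table_from_xy(np.array([mx]), np.array([0.0]))
    assert assign_hex(t, g).tolist() == [[0, 0]]


def test_partition_counts_conserved():
    rng = np.random.default_rng(5)
    g = build_grid((0, 4), (0, 4), nbins=6)
    t = table_from_xy(rng.uniform(0, 4, 500), rng.uniform(0, 4, 500))
    agg = aggregate(t, g)
    assert agg.total_count == 500


def test_refining_nbins_does_not_decrease_occupancy():
    rng = np.random.default_rng(9)
    xs, ys = rng.uniform(0, 10, 800), rng.uniform(0, 10, 800)
    t = table_from_xy(xs, ys)
    occ = []
    for nbins in (5, 10, 20, 40):
        g = build_grid((0, 10), (0, 10), nbins=nbins)
        occ.append(len(aggregate(t, g).cells))
    assert occ == sorted(occ)


# ---------------------------------------------------------------- aggregate

def test_majority_and_tally_small_cell():
    g = build_grid((0, 10), (0, 10), nbins=2)  # huge cells
    cx, cy = g.center(0, 0)
    xs = np.array([cx, cx + 0.01, cx - 0.01])
    ys = np.array([cy, cy, cy])
    t = table_from_xy(xs, ys, lab=("categorical", ["A", "A", "B"]))
    agg = aggregate(t, g, categorical=["lab"])
    s = agg.cells[(0, 0)]
    assert s.count == 3
    assert s.tally["lab"] == {"A": 2, "B": 1}
    assert s.majority["lab"] == "A"


def test_majority_tie_breaks_lexicographically():
    g = build_grid((0, 10), (0, 10), nbins=2)
    cx, cy = g.center(0, 0)
    t = table_from_xy(
        np.array([cx, cx + 0.01]), np.array([cy, cy]),
        lab=("categorical", ["B", "A"]),
    )
    agg = aggregate(t, g, categorical=["lab"])
    assert agg.cells[(0, 0)].majority["lab"] == "A"


def test_aggregate_matches_group_by_oracle():
    rng = np.random.default_rng(11)
    n = 500
    xs = rng.uniform(0, 6, n)
    ys = rng.uniform(0, 6, n)
    labs = [rng.choice(["A", "B", "C"]) for _ in range(n)]
    vals = rng.normal(size=n)
    t = table_from_xy(
        xs, ys, lab=("categorical", labs), v=("continuous", list(vals))
    )
    g = build_grid((0, 6), (0, 6), nbins=8)
    agg = aggregate(t, g, continuous=["v"], categorical=["lab"])

    assigned = oracle_assign(xs, ys, g)
    groups = {}
    for i, cell in enumerate(assigned):
        groups.setdefault(cell, []).append(i)
    assert set(agg.cells) == set(groups)
    for cell, idx in groups.items():
        s = agg.cells[cell]
        assert s.count == len(idx)
        tally = Counter(labs[i] for i in idx)
        assert s.tally["lab"] == dict(tally)
        top = max(tally.values())
        assert s.majority["lab"] == min(
            l for l, c in tally.items() if c == top
        )
        mean = sum(vals[i] for i in idx) / len(idx)
        assert s.means["v"] == pytest.approx(mean, rel=1e-12)


def test_aggregate_mean_skips_missing_values():
    g = build_grid((0, 10), (0, 10), nbins=2)
    cx, cy = g.center(0, 0)
    t = table_from_xy(
        np.array([cx, cx + 0.01, cx - 0.01]), np.array([cy, cy, cy]),
        v=("continuous", [1.0, None, 3.0]),
    )
    agg = aggregate(t, g, continuous=["v"])
    assert agg.cells[(0, 0)].means["v"] == pytest.approx(2.0)


def test_aggregate_unknown_column_errors():
    t = table_from_xy(np.array([0.5]), np.array([0.5]))
    g = build_grid((0, 1), (0, 1), nbins=2)
    with pytest.raises(KeyError, match="nope"):
        aggregate(t, g, continuous=["nope"])


# ---------------------------------------------------------------- boundaries

def test_single_cell_emits_six_segments():
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=1)
    agg = make_aggregate(g, {(0, 0): "A"})
    b = extract_label_boundaries(agg, g, "lab")
    assert len(b.segments["A"]) == 6


def test_two_adjacent_same_label_share_suppressed_edge():
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=1)
    agg = make_aggregate(g, {(0, 0): "A", (1, 0): "A"})
    b = extract_label_boundaries(agg, g, "lab")
    assert len(b.segments["A"]) == 10


def test_two_adjacent_different_labels_emit_twelve_segments():
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=1)
    agg = make_aggregate(g, {(0, 0): "A", (1, 0): "B"})
    b = extract_label_boundaries(agg, g, "lab")
    assert len(b.segments["A"]) == 6
    assert len(b.segments["B"]) == 6
    # the shared edge appears once in EACH label's set
    shared = canon_segments(b.segments, g.size)
    assert len(shared["A"] & shared["B"]) == 1


def test_boundaries_match_per_edge_oracle_on_random_patterns():
    rng = np.random.default_rng(3)
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=12)
    for _ in range(25):
        majorities = {}
        for q in range(12):
            for r in range(12):
                if rng.random() < 0.5:
                    majorities[(q, r)] = str(rng.choice(["A", "B", "C"]))
        if not majorities:
            continue
        agg = make_aggregate(g, majorities)
        got = canon_segments(
            extract_label_boundaries(agg, g, "lab").segments, g.size
        )
        want = canon_segments(oracle_boundaries(agg, g, "lab"), g.size)
        assert got == want


def test_boundary_closure_even_vertex_degree():
    """A simply-connected same-label region has a cycle for a boundary:
    every vertex is met an even number of times."""
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=1)
    blob = {(0, 0), (1, 0), (0, 1), (1, 1), (-1, 1), (2, 0), (1, -1)}
    agg = make_aggregate(g, {c: "A" for c in blob})
    b = extract_label_boundaries(agg, g, "lab")
    deg = Counter()
    for a, bb in b.segments["A"]:
        deg[quantize(a, g.size)] += 1
        deg[quantize(bb, g.size)] += 1
    assert all(d % 2 == 0 for d in deg.values())


def test_different_label_regions_never_share_interior_edges():
    """Unlike convex hulls, two labels' regions can only meet at their
    common frontier: no edge interior to one label's region ever appears
    in another label's set."""
    rng = np.random.default_rng(13)
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=10)
    majorities = {
        (q, r): ("A" if q < 5 else "B")
        for q in range(10) for r in range(10) if rng.random() < 0.8
    }
    agg = make_aggregate(g, majorities)
    b = extract_label_boundaries(agg, g, "lab")
    segs = canon_segments(b.segments, g.size)
    # interior edges (between two occupied same-label cells) of each label
    for cell, lab in majorities.items():
        verts = oracle_vertices(g, *cell)
        cx, cy = g.center(*cell)
        for k in range(6):
            a, bb = verts[k], verts[(k + 1) % 6]
            seg = tuple(sorted((quantize(a, g.size), quantize(bb, g.size))))
            # find neighbor by reflection
            mx, my = (a[0] + bb[0]) / 2, (a[1] + bb[1]) / 2
            nbc = quantize((2 * mx - cx, 2 * my - cy), g.size)
            nb = next(
                (c for c in majorities if quantize(g.center(*c), g.size) == nbc),
                None,
            )
            if nb is not None and majorities[nb] == lab:
                for other, ss in segs.items():
                    assert seg not in ss


def test_boundary_variable_must_be_aggregated():
    g = HexGrid(size=1.0, origin=(0.0, 0.0), nbins=1)
    agg = make_aggregate(g, {(0, 0): "A"})
    with pytest.raises(KeyError, match="other"):
        extract_label_boundaries(agg, g, "other")
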