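"""Synthetic scenes with known ground truth.

Two generators emulate the package's two intended use cases so that
every plotting and binning behavior is testable without downloading
real data:

* :func:`make_layered_tissue` — a Visium-like hexagonal spot lattice
  over a cortex-like tissue section with horizontal layer bands
  (L1..L{n-1} plus white matter, WM) and a per-spot categorical gene
  "colocalization status" in {none, geneA, geneB, both}, where the
  probability of "both" is multiplied by an enrichment factor in one
  designated layer.

* :func:`make_mixture_embedding` — a 2D Gaussian-mixture embedding
  (UMAP analogue) with cluster labels and a continuous "expr" variable
  drawn from a higher-mean lognormal in designated clusters.

All randomness flows through numpy's PCG64 generator seeded explicitly,
so a (seed, parameters) pair always regenerates the identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .core import AnnotationColumn, PointTable, ValidationError, validate_table

__all__ = [
    "SyntheticScene",
    "make_layered_tissue",
    "make_mixture_embedding",
    "well_separated_mask",
    "COLOC_LEVELS",
]

#: colocalization states: neither gene above threshold, one, or both
COLOC_LEVELS = ("none", "geneA", "geneB", "both")

#: baseline colocalization state probabilities in unenriched layers
BASELINE_COLOC_P = {"none": 0.70, "geneA": 0.12, "geneB": 0.12, "both": 0.06}

#: Visium-like lattice center-to-center spacing, data units
LATTICE_SPACING = 100.0

#: lognormal (mu, sigma) of the log for baseline / elevated expression
EXPR_BASE_LOGNORMAL = (0.5, 0.5)
EXPR_HIGH_LOGNORMAL = (2.0, 0.5)


@dataclass(frozen=True)
class SyntheticScene:
    """A generated table plus the parameters that produced it."""

    table: PointTable
    truth: Mapping[str, object]
    seed: int


def _layer_labels(n_layers: int) -> list[str]:
    return [f"L{i}" for i in range(1, n_layers)] + ["WM"]


def make_layered_tissue(
    n_spots: int = 4000,
    n_layers: int = 7,
    enriched_layer: str | int = "L6",
    enrichment: float = 4.0,
    seed: int = 0,
) -> SyntheticScene:
    """Generate a layered cortex-like tissue section on a spot lattice.

    Spots sit on a hexagonal lattice (odd rows offset by half a spacing)
    filling a roughly square rectangle; the "layer" annotation is
    assigned by ``n_layers`` horizontal bands of equal height, labeled
    top to bottom L1..L{n-1} then WM (image-mode coordinates, y down).
    Each spot draws a "coloc_status" from the baseline distribution,
    except in the enriched layer where Pr(both) is multiplied by
    ``enrichment`` and the distribution renormalized.

    ``enriched_layer`` may be a label ("L6") or a 1-based band index.
    """
    if n_layers < 2:
        raise ValidationError(f"n_layers must be >= 2, got {n_layers}")
    if not enrichment > 1:
        raise ValidationError(f"enrichment must exceed 1, got {enrichment}")
    labels = _layer_labels(n_layers)
    if isinstance(enriched_layer, (int, np.integer)):
        if not 1 <= enriched_layer <= n_layers:
            raise ValidationError(
                f"enriched_layer index {enriched_layer} outside 1..{n_layers}"
            )
        enriched = labels[enriched_layer - 1]
    else:
        if enriched_layer not in labels:
            raise ValidationError(
                f"enriched_layer {enriched_layer!r} not one of {labels}"
            )
        enriched = str(enriched_layer)

    rng = np.random.Generator(np.random.PCG64(seed))

    # hexagonal lattice: row pitch spacing*sqrt(3)/2, odd rows offset
    ncols = max(1, math.ceil(math.sqrt(n_spots)))
    row_pitch = LATTICE_SPACING * math.sqrt(3.0) / 2.0
    xs, ys = [], []
    row = 0
    while len(xs) < n_spots:
        offset = (LATTICE_SPACING / 2.0) if row % 2 else 0.0
        for c in range(ncols):
            xs.append(offset + c * LATTICE_SPACING)
            ys.append(row * row_pitch)
            if len(xs) >= n_spots:
                break
        row += 1
    x = np.array(xs)
    y = np.array(ys)

    y_min, y_max = float(y.min()), float(y.max())
    band_h = (y_max - y_min) / n_layers or 1.0
    band_edges = [y_min + i * band_h for i in range(n_layers + 1)]
    band_idx = np.minimum(((y - y_min) / band_h).astype(int), n_layers - 1)
    layer = np.array([labels[i] for i in band_idx], dtype=object)

    base_p = np.array([BASELINE_COLOC_P[l] for l in COLOC_LEVELS])
    enr_p = base_p.copy()
    enr_p[COLOC_LEVELS.index("both")] *= enrichment
    enr_p = enr_p / enr_p.sum()

    status = np.empty(n_spots, dtype=object)
    for i in range(n_spots):
        p = enr_p if layer[i] == enriched else base_p
        status[i] = COLOC_LEVELS[rng.choice(len(COLOC_LEVELS), p=p)]

    width = len(str(n_spots))
    ids = np.array([f"spot-{i:0{width}d}" for i in range(n_spots)], dtype=object)
    table = PointTable(point_ids=ids, x=x, y=y, coord_mode="image")
    table = table.with_annotation(
        AnnotationColumn.from_raw("layer", list(layer), kind="categorical")
    )
    table = table.with_annotation(
        AnnotationColumn.from_raw("coloc_status", list(status), kind="categorical")
    )
    truth = {
        "kind": "layered_tissue",
        "labels": labels,
        "band_edges": band_edges,
        "enriched_layer": enriched,
        "enrichment": float(enrichment),
        "baseline_p": dict(BASELINE_COLOC_P),
        "enriched_p": {l: float(p) for l, p in zip(COLOC_LEVELS, enr_p)},
        "spacing": LATTICE_SPACING,
        # expected ratio Pr(both | enriched) / Pr(both | other)
        "both_ratio": float(enr_p[COLOC_LEVELS.index("both")]
                            / BASELINE_COLOC_P["both"]),
    }
    return SyntheticScene(table=validate_table(table), truth=truth, seed=seed)


def make_mixture_embedding(
    n_cells: int = 5000,
    k: int = 5,
    expr_high_clusters: Iterable[int] = (1,),
    seed: int = 0,
    radius: float = 10.0,
    sigma: float = 1.0,
) -> SyntheticScene:
    """Generate a 2D Gaussian-mixture embedding with cluster labels.

    Cluster means sit evenly on a circle of the given radius with
    isotropic covariance ``sigma**2 * I`` and equal mixing proportions;
    labels are C1..Ck.  The continuous "expr" annotation is lognormal:
    log-parameters ``EXPR_HIGH_LOGNORMAL`` in the 1-based clusters listed
    in ``expr_high_clusters``, ``EXPR_BASE_LOGNORMAL`` elsewhere.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    high = {int(c) for c in expr_high_clusters}
    if not high <= set(range(1, k + 1)):
        raise ValidationError(
            f"expr_high_clusters {sorted(high)} not a subset of 1..{k}"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    angles = 2 * np.pi * np.arange(k) / k
    means = np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])
    cov = (sigma ** 2) * np.eye(2)

    comp = rng.integers(0, k, size=n_cells)
    noise = rng.normal(size=(n_cells, 2)) * sigma
    xy = means[comp] + noise

    mu_b, sd_b = EXPR_BASE_LOGNORMAL
    mu_h, sd_h = EXPR_HIGH_LOGNORMAL
    is_high = np.array([(c + 1) in high for c in comp])
    logs = rng.normal(size=n_cells)
    expr = np.where(
        is_high, np.exp(mu_h + sd_h * logs), np.exp(mu_b + sd_b * logs)
    )

    labels = [f"C{c + 1}" for c in comp]
    width = len(str(n_cells))
    ids = np.array([f"cell-{i:0{width}d}" for i in range(n_cells)], dtype=object)
    table = PointTable(point_ids=ids, x=xy[:, 0], y=xy[:, 1], coord_mode="cartesian")
    table = table.with_annotation(
        AnnotationColumn.from_raw("cluster", labels, kind="categorical")
    )
    table = table.with_annotation(
        AnnotationColumn.from_raw("expr", [float(v) for v in expr])
    )
    truth = {
        "kind": "mixture_embedding",
        "means": means,
        "cov": cov,
        "sigma": float(sigma),
        "proportions": [1.0 / k] * k,
        "expr_high_clusters": sorted(high),
        "lognormal_base": (mu_b, sd_b),
        "lognormal_high": (mu_h, sd_h),
        # closed-form lognormal means, exp(mu + sigma^2/2)
        "expr_mean_base": float(np.exp(mu_b + sd_b ** 2 / 2)),
        "expr_mean_high": float(np.exp(mu_h + sd_h ** 2 / 2)),
        "component": comp,
    }
    return SyntheticScene(table=validate_table(table), truth=truth, seed=seed)


def well_separated_mask(scene: SyntheticScene, n_sigma: float = 2.0) -> np.ndarray:
    """Boolean mask of cells lying at least ``n_sigma`` standard
    deviations from the mean of every cluster other than their own."""
    truth = scene.truth
    if truth.get("kind") != "mixture_embedding":
        raise ValidationError("well_separated_mask expects a mixture embedding scene")
    means = np.asarray(truth["means"])
    sigma = float(truth["sigma"])
    comp = np.asarray(truth["component"])
    xy = np.column_stack([scene.table.x, scene.table.y])
    d = np.linalg.norm(xy[:, None, :] - means[None, :, :], axis=2)
    d[np.arange(len(comp)), comp] = np.inf  # ignore own cluster
    return d.min(axis=1) >= n_sigma * sigma
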