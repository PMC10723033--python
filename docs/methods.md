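# Methods

## The visualization model

`spotglass` renders up to three variables on one set of 2D marks by
assigning each variable a distinct aesthetic channel, chosen so the
channels segregate perceptually (figure–ground segmentation):

| role   | aesthetic            | variable kind              |
|--------|----------------------|----------------------------|
| ground | spot outline color   | categorical                |
| figure | spot fill            | continuous or categorical  |
| symbol | glyph overlay        | categorical (subset map)   |

A single disc per spot carries both the stroke (ground) and the fill
(figure); we deliberately do not draw two concentric discs, which would
double the element count for no perceptual gain. The outline works
because a thin colored boundary induces a perceived surface color (the
watercolor effect), so the ground variable reads as a background even
when adjacent spots leave no literal background to paint. Symbols are
separate artists drawn strictly above every disc, and in SVG output
they appear later in document order, which makes the z-order contract
machine-checkable.

Rendering invariants that tests rely on:

* each disc is a `<g id="spot-<id>">`-tagged element whose CSS style
  carries both `fill:` and `stroke:`; ground-only figures emit
  `fill: none`;
* spots are drawn in ascending point-id order, so overlap resolution is
  deterministic;
* level → color assignment is by sorted level order over a
  colorblind-safe cycle (Okabe–Ito), so palettes are reproducible
  regardless of row order;
* `coord_mode="image"` (microscopy pixel) tables are flipped on the y
  axis at render time only; stored coordinates are never mutated, so
  file round-trips are exact.

## Hexagonal binning

Pointy-top hexagons, axial coordinates $(q,r)$, centers
$x = x_0 + s\sqrt3(q + r/2)$, $y = y_0 + \frac32 s r$. The
user-facing granularity knob is `nbins`, the number of hexagon columns
spanning the x extent: $s = \Delta x / (n_\text{bins}\sqrt3)$ (a
pointy-top hexagon is $s\sqrt3$ wide). The origin is the extent's
lower-left corner.

Point assignment converts to fractional axial coordinates and applies
cube rounding, which yields the nearest center for all interior points.
Points exactly equidistant between centers (edge midpoints, vertices)
are resolved to the lexicographically smallest tied $(q,r)$, evaluated
by comparing the rounded cell and its six neighbors within a relative
tolerance of $10^{-9}s$; this makes assignment a pure function of
coordinates, independent of input order. Tests verify assignment
against a brute-force nearest-center search over an exhaustive
candidate list.

Aggregation per occupied cell: point count, arithmetic mean of each
continuous variable over non-missing members (NaN, rendered neutral
grey, if all members are missing), and per categorical variable a full
label tally plus the majority label, with ties again broken
lexicographically. Cells with no members are absent from the result,
not zero-filled — the aggregate is sparse by construction, and the
partition property (cell counts sum to the point count) is asserted in
tests.

## Label-region boundaries

For a chosen categorical variable, each occupied cell contributes each
of its six edges to its majority label's segment set **iff** the cell
across that edge is unoccupied or has a different majority. Interior
edges of a same-label region are suppressed, so a simply connected
region's boundary forms closed cycles (every vertex has even degree —
a tested invariant). An edge between two occupied cells of different
majorities is emitted once into *each* label's set (two-sided
convention; both are drawn full width, later label on top by sorted
order). Because emission is driven by the majority partition, two
labels' region interiors can never overlap — the property that makes
these outlines preferable to convex hulls, and the property the
boundary oracle test checks on random occupancy patterns.

Vertex coordinates are quantized to $10^{-6}s$ so a vertex computed
from two neighboring cells' centers compares equal despite float noise.

## Synthetic scenes

The generators produce the fixtures every test and the acceptance
script run on; all randomness flows through numpy's PCG64 seeded
explicitly, so a (seed, parameters) pair regenerates byte-identical
tables.

**Layered tissue** (`make_layered_tissue`): spots on a hexagonal
lattice with 100-unit center-to-center spacing (a convenient round
number standing in for spot-array geometry) filling a roughly square
rectangle, image-mode coordinates. The `layer` annotation divides the
y range into equal-height bands labeled L1..L{n−1} then WM, emulating
cortical layers over white matter. Each spot draws a `coloc_status`
from {none, geneA, geneB, both} with baseline probabilities
(0.70, 0.12, 0.12, 0.06); in the enriched layer (default L6) the
probability of `both` is multiplied by the enrichment factor (default
4) and the vector renormalized. The truth record stores the implied
ratio Pr(both | enriched)/Pr(both | other) = e/(1+(e−1)p), which the
empirical ratio at n = 20 000 spots recovers within ±10% — a sampling
regime chosen so the check is sharp without being slow.

**Mixture embedding** (`make_mixture_embedding`): k cluster means
evenly spaced on a circle of radius 10 with isotropic unit covariance —
adjacent means sit ~11.8σ apart for k = 5, a deliberately
well-separated regime so that per-hexagon majority labels should
recover true labels almost perfectly for cells ≥2σ from every other
cluster mean (the tested bound is ≥90%). The `expr` annotation is
lognormal, log-parameters (0.5, 0.5) baseline and (2.0, 0.5) in
designated high clusters; the closed-form mean exp(μ+σ²/2) anchors a
consistency test when no cluster is elevated.

What the generators do *not* emulate: transcriptome-wide counts,
spatial autocorrelation, dropout, batch structure, or the cell–cell
communication analysis that would produce real colocalization calls
(colocalization status is an upstream input here, never computed).
Passing tests therefore demonstrate geometric and rendering
correctness and parameter recovery under clean conditions, not
robustness to real-data noise.

## Numerical and design choices

* Kind inference: numeric values → continuous (integer counts
  included), strings/booleans → categorical; mixed input is an error
  unless an explicit override is given. Integer cluster ids therefore
  need an override to plot as categories.
* Missing annotation values are allowed (explicit mask, not NaN
  sentinels) and render neutral grey `#bdbdbd`; coordinates may never
  be missing.
* A constant continuous column maps every spot to the colormap
  midpoint, avoiding a divide-by-zero in range normalization.
* Default ground stroke width is 15% of the spot diameter — thin
  enough that the fill remains the perceptual figure.
* Sparse matrix absences read as 0 (count semantics), not missing.
* The CLI's exit codes are 0/1/2 (success / environment / usage);
  subcommand failures print a single-line message, with stack traces
  only at `--log-level debug`.

Problem sizes in the test suite and acceptance script (2 000-point
assignment oracle on a 20×20 grid, 100 random boundary patterns on
≤12×12 grids, 10 000-cell recovery runs, 20 000-spot enrichment runs)
were chosen as the smallest sizes at which each property is measured
sharply; all complete in seconds on one core.

## Known limitations

* No interactive output, hatching fills, polygon (cell-morphology)
  marks, or 3D coordinates.
* No within-hexagon subdivision for mixed-label cells; intermixing is
  surfaced through the stored tally instead, and interpretation near
  cluster borders should consult it.
* Occupied-cell count is not formally monotone under `nbins`
  refinement (hex grids are not nested); it is monotone in practice at
  realistic densities, and tested as such on random fixtures.
* The Visium reader ingests positions only; expression must be joined
  via the MTX reader (`attach_annotation`) — there is no h5/h5ad path.
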