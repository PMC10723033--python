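# spotglass

Layered spot maps and hexbin summaries for multi-variable 2D omics data.

Spatial transcriptomics and single-cell analyses constantly need to show
two or three variables at once on the same 2D coordinates: gene
expression *and* spatial domain on a Visium tissue section, or cluster
membership *and* marker expression on a UMAP. The usual answer — two
plots side by side — forces the reader to mentally align them.
`spotglass` puts the variables on one set of marks instead, using
figure–ground segmentation:

* **figure** — one variable fills each spot's interior (continuous
  colormap or discrete palette);
* **ground** — a second, categorical variable colors a thin outline
  around each spot (a thin colored boundary is perceptually read as a
  background color — the watercolor effect — so it works even when
  spots nearly touch);
* **symbol** — an optional third, categorical variable draws a glyph
  (`+ * x o triangle`) on selected spots.

For embeddings, where overplotting makes per-cell marks useless,
`spotglass` bins the plane into pointy-top hexagons and summarizes each
occupied cell: point count, arithmetic mean of each continuous variable,
and the majority label of each categorical variable (ties go to the
lexicographically smallest label). Each label's territory is outlined
by exactly the hexagon edges that separate it from other labels or
empty space. Because these regions partition the occupied cells, their
interiors can never overlap — unlike convex-hull cluster annotations,
which routinely intersect and leave hexagon membership ambiguous.

Hexagons use axial coordinates $(q, r)$ with centers at

$$x = x_0 + s\sqrt{3}\,(q + r/2), \qquad y = y_0 + \tfrac{3}{2}\,s\,r,$$

for circumradius $s = \text{x-range}/(n_\text{bins}\sqrt{3})$; points
are assigned to the nearest center via fractional axial coordinates and
cube rounding, with exact ties resolved to the lexicographically
smallest $(q, r)$ so results are independent of row order.

## Worked example

Generate the two bundled synthetic scenes (a layered cortex-like tissue
with a colocalization status per spot, and a 5-cluster Gaussian-mixture
embedding with cluster-elevated expression) and render them:

```
$ spotglass demo --out-dir demo --seed 42
INFO spotglass: wrote demo/tissue.csv
INFO spotglass: wrote demo/embedding.csv
INFO spotglass: wrote demo/tissue_domains.svg
INFO spotglass: wrote demo/tissue_coloc.svg
INFO spotglass: wrote demo/tissue_unified.svg
INFO spotglass: wrote demo/embedding_hex.svg
```

`tissue_domains.svg` / `tissue_coloc.svg` are the traditional
side-by-side pair (one variable each); `tissue_unified.svg` shows both
at once — cortex layers as spot outlines, colocalization status as spot
fill, with a `+` marking spots where both genes are detected.
`embedding_hex.svg` shows per-hexagon mean expression with
majority-cluster boundary outlines.

The same plots from your own files:

```
$ spotglass spot-plot pts.csv --ground layer --fill coloc_status \
      --symbol coloc_status:both:+ -o unified.svg
$ spotglass hex-plot demo/embedding.csv --nbins 30 --fill expr \
      --label cluster --table-out agg.tsv -o hex.svg
INFO spotglass: aggregated 3000 points into 257 occupied hexagons
INFO spotglass: wrote agg.tsv
INFO spotglass: wrote hex.svg
```

`agg.tsv` holds the per-cell summary; the full tally is kept so mixed
cells are inspectable rather than hidden behind the majority label:

```
q    r    count  mean_expr           majority_cluster  tally_cluster
-15  29   1      3.721474933564472   C3                C3:1
-13  26   1      0.6688576299851299  C3                C3:1
```

The `count` column always sums to the number of input points (3000
here): binning is a partition.

Library use mirrors the CLI: `read_points_csv` /
`read_visium_positions` / `read_mtx_expression` build a `PointTable`;
`new_plot` + `add_ground` / `add_fill` / `add_symbol` + `render`
compose spot maps; `build_grid` / `aggregate` /
`extract_label_boundaries` / `hex_plot` + `render_hex` produce hex
summaries.

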