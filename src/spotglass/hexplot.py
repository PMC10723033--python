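"""Rendering of hexbin aggregates: filled hexagons + label-region outlines."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib as mpl
import numpy as np
from matplotlib.cm import ScalarMappable
from matplotlib.collections import LineCollection
from matplotlib.colors import Normalize, to_hex
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Polygon

from .core import NEUTRAL_GREY, ValidationError
from .hexbin import HexAggregate, RegionBoundary, hex_cell_vertices
from .style import StyleConfig, continuous_cmap, discrete_colors

__all__ = ["HexFigure", "hex_plot", "render_hex"]


@dataclass(frozen=True)
class HexFigure:
    """A renderable hex summary: per-cell fills plus boundary strokes."""

    agg: HexAggregate
    boundaries: RegionBoundary | None
    fill_variable: str
    title: str = ""
    show_legend: bool = True
    width_px: int = 900
    height_px: int = 900
    background: str = "white"
    cmap: object = None
    palette: object = None


def hex_plot(
    agg: HexAggregate,
    boundaries: RegionBoundary | None,
    fill_variable: str,
    **kwargs,
) -> HexFigure:
    """Compose a hex figure: hexagon fills colored by the per-cell mean of
    ``fill_variable`` (continuous colormap over the occupied cells'
    range), overlaid with label-region boundary segments stroked by label
    color, strictly above the fills."""
    if fill_variable not in agg.continuous:
        raise KeyError(
            f"variable {fill_variable!r} was not aggregated as continuous; "
            f"have: {sorted(agg.continuous)}"
        )
    return HexFigure(
        agg=agg, boundaries=boundaries, fill_variable=fill_variable, **kwargs
    )


def render_hex(hf: HexFigure, path: str | Path, format: str | None = None) -> Path:
    """Render to png/pdf/svg.  In SVG output each hexagon patch carries a
    ``hex-<q>-<r>`` gid and each label's boundary collection a
    ``boundary-<label>`` gid; boundaries are emitted after fills."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "png").lower()
    if fmt not in ("png", "pdf", "svg"):
        raise ValidationError(f"unsupported format {fmt!r}")
    agg, grid = hf.agg, hf.agg.grid
    if not agg.cells:
        raise ValidationError("cannot render an empty aggregate")

    style = StyleConfig()
    cmap = continuous_cmap(hf.cmap)
    means = {cell: s.means[hf.fill_variable] for cell, s in agg.cells.items()}
    finite = [m for m in means.values() if math.isfinite(m)]
    if finite and max(finite) > min(finite):
        norm = Normalize(min(finite), max(finite))
    else:
        norm = None  # constant or all-missing: midpoint / grey

    dpi = 100.0
    mplfig = Figure(figsize=(hf.width_px / dpi, hf.height_px / dpi), dpi=dpi)
    mplfig.patch.set_facecolor(hf.background)
    ax = mplfig.add_subplot(111)
    ax.set_facecolor(hf.background)
    ax.set_aspect("equal", adjustable="box")
    ax.set_xticks([])
    ax.set_yticks([])
    for s in ax.spines.values():
        s.set_visible(False)
    if hf.title:
        ax.set_title(hf.title)

    centers = np.array([grid.center(q, r) for q, r in agg.cells])
    pad = 2.0 * grid.size
    ax.set_xlim(centers[:, 0].min() - pad, centers[:, 0].max() + pad)
    ax.set_ylim(centers[:, 1].min() - pad, centers[:, 1].max() + pad)

    for (q, r) in sorted(agg.cells):
        m = means[(q, r)]
        if not math.isfinite(m):
            fc = style.get("missing_color", NEUTRAL_GREY)
        elif norm is None:
            fc = to_hex(cmap(0.5))
        else:
            fc = to_hex(cmap(float(norm(m))))
        patch = Polygon(
            hex_cell_vertices(grid, q, r),
            closed=True,
            facecolor=fc,
            edgecolor="none",
            zorder=2,
        )
        patch.set_gid(f"hex-{q}-{r}")
        ax.add_artist(patch)  # limits set above; skip per-patch autoscaling

    handles = []
    if hf.boundaries is not None and hf.boundaries.segments:
        colors = discrete_colors(hf.boundaries.labels, hf.palette)
        # later label on top by sorted order
        for z, lab in enumerate(sorted(hf.boundaries.labels)):
            segs = [np.array(seg) for seg in sorted(hf.boundaries.segments[lab])]
            lc = LineCollection(
                segs, colors=colors[lab], linewidths=1.8, zorder=3 + z * 0.01,
                capstyle="round",
            )
            lc.set_gid(f"boundary-{lab}")
            ax.add_collection(lc)
            handles.append(Line2D([], [], color=colors[lab], label=lab))

    if hf.show_legend:
        sm = ScalarMappable(norm=norm or Normalize(0, 1), cmap=cmap)
        mplfig.colorbar(sm, ax=ax, shrink=0.6, label=hf.fill_variable)
        if handles:
            ax.legend(
                handles=handles, loc="center left", bbox_to_anchor=(1.25, 0.5),
                frameon=False, fontsize=8, title="majority",
            )

    try:
        # keep SVG text as <text> (not glyph paths) so legends are
        # textually checkable; drop the date stamp for reproducible bytes
        kw = {"metadata": {"Date": None}} if fmt == "svg" else {}
        with mpl.rc_context({"svg.fonttype": "none", "svg.hashsalt": "spotglass"}):
            mplfig.savefig(path, format=fmt, bbox_inches="tight", **kw)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path
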