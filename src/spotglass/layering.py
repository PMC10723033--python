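"""Figure-ground-symbol layered spot plots.

The plot encodes up to three variables on one set of spots by exploiting
figure-ground segmentation: the *figure* variable fills each spot's
interior, the *ground* variable colors a thin outline around the spot
(the watercolor effect lets a thin colored boundary stand in for a
background color when neighboring spots leave no room to paint actual
background), and an optional *symbol* variable draws a glyph on top of
selected spots.  One disc per spot carries both stroke (ground) and fill
(figure); glyphs are separate artists drawn strictly above the discs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np

matplotlib.use("Agg", force=False)

from matplotlib.colors import Normalize, to_hex
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Circle, Patch

from .core import CATEGORICAL, CONTINUOUS, NEUTRAL_GREY, PointTable, ValidationError, validate_table
from .style import StyleConfig, continuous_cmap, discrete_colors

__all__ = [
    "GLYPHS",
    "LayerSpec",
    "FigureSpec",
    "new_plot",
    "add_ground",
    "add_fill",
    "add_symbol",
    "render",
]

#: glyph vocabulary → matplotlib marker
GLYPHS = {"+": "+", "*": "*", "x": "x", "o": "o", "triangle": "^"}

_ROLE_RANK = {"ground": 0, "figure": 1, "symbol": 2}

#: default outline thickness as a fraction of spot diameter; thin so the
#: fill stays the perceptual figure and the outline reads as ground
DEFAULT_STROKE_FRAC = 0.15


@dataclass(frozen=True)
class LayerSpec:
    """One aesthetic layer bound to an annotation variable.

    ``role`` is ``ground`` (outline color, categorical), ``figure``
    (fill, either kind) or ``symbol`` (glyph overlay, categorical).
    """

    role: str
    variable: str
    palette: object = None
    stroke_width: float | None = None  # data units; ground only
    glyph_map: Mapping[str, str] = field(default_factory=dict)  # symbol only
    z_rank: int = 0

    def __post_init__(self):
        if self.role not in _ROLE_RANK:
            raise ValidationError(f"unknown layer role {self.role!r}")
        for lev, g in self.glyph_map.items():
            if g not in GLYPHS:
                raise ValidationError(
                    f"glyph {g!r} for level {lev!r} not one of {sorted(GLYPHS)}"
                )


@dataclass(frozen=True)
class FigureSpec:
    """An ordered layer stack bound to a point table."""

    table: PointTable
    spot_diameter: float
    layers: tuple[LayerSpec, ...] = ()
    title: str = ""
    show_legend: bool = True
    width_px: int = 900
    height_px: int = 900
    background: str = "white"

    def layer(self, role: str) -> LayerSpec | None:
        for l in self.layers:
            if l.role == role:
                return l
        return None


def new_plot(table: PointTable, spot_diameter: float, **kwargs) -> FigureSpec:
    """Start an empty layered plot over a validated table."""
    validate_table(table)
    if not spot_diameter > 0:
        raise ValidationError(f"spot_diameter must be positive, got {spot_diameter}")
    return FigureSpec(table=table, spot_diameter=float(spot_diameter), **kwargs)


def _add_layer(fig: FigureSpec, layer: LayerSpec) -> FigureSpec:
    if fig.layer(layer.role) is not None:
        raise ValidationError(f"a {layer.role} layer is already present")
    layers = tuple(
        sorted(fig.layers + (layer,), key=lambda l: _ROLE_RANK[l.role])
    )
    return replace(fig, layers=layers)


def _require_kind(fig: FigureSpec, variable: str, kind: str, role: str) -> None:
    col = fig.table.annotation(variable)  # raises KeyError on unknown name
    if col.kind != kind:
        raise ValidationError(
            f"{role} layer requires a {kind} variable; {variable!r} is {col.kind}"
        )


def add_ground(
    fig: FigureSpec,
    variable: str,
    palette=None,
    stroke_width: float | None = None,
) -> FigureSpec:
    """Add the ground layer: unfilled disc outlines colored by a
    categorical variable.  The interior stays whatever other layers
    paint (transparent if none)."""
    _require_kind(fig, variable, CATEGORICAL, "ground")
    if stroke_width is not None and not stroke_width > 0:
        raise ValidationError("stroke_width must be positive")
    layer = LayerSpec(
        role="ground",
        variable=variable,
        palette=palette,
        stroke_width=stroke_width,
        z_rank=_ROLE_RANK["ground"],
    )
    return _add_layer(fig, layer)


def add_fill(fig: FigureSpec, variable: str, palette=None) -> FigureSpec:
    """Add the figure layer: spot interiors filled by a continuous
    colormap over the observed [min, max], or a discrete palette for a
    categorical variable."""
    fig.table.annotation(variable)  # name check; either kind accepted
    layer = LayerSpec(
        role="figure", variable=variable, palette=palette, z_rank=_ROLE_RANK["figure"]
    )
    return _add_layer(fig, layer)


def add_symbol(fig: FigureSpec, variable: str, glyph_map: Mapping[str, str]) -> FigureSpec:
    """Add the symbol layer: a glyph centered on each spot whose level is
    in ``glyph_map``; uncovered levels draw nothing."""
    _require_kind(fig, variable, CATEGORICAL, "symbol")
    layer = LayerSpec(
        role="symbol",
        variable=variable,
        glyph_map=dict(glyph_map),
        z_rank=_ROLE_RANK["symbol"],
    )
    return _add_layer(fig, layer)


def _continuous_fill_colors(col, cmap, missing_color) -> list[str]:
    vals = np.asarray(col.values, dtype=float)
    ok = ~col.missing & np.isfinite(vals)
    if ok.any():
        lo, hi = float(vals[ok].min()), float(vals[ok].max())
    else:
        lo = hi = 0.0
    if hi > lo:
        norm = Normalize(lo, hi)
        frac = norm(vals)
    else:
        # constant column: every spot maps to the colormap midpoint
        frac = np.full(len(vals), 0.5)
    out = []
    for f, m in zip(frac, col.missing):
        out.append(missing_color if m else to_hex(cmap(float(f))))
    return out


def _resolve_spot_paints(fig: FigureSpec, style: StyleConfig):
    """Per-spot (facecolor, edgecolor) plus legend handles per layer."""
    n = fig.table.n_points
    missing_color = style.get("missing_color", NEUTRAL_GREY)
    face = ["none"] * n
    edge = ["none"] * n
    handles: list = []

    fig_layer = fig.layer("figure")
    if fig_layer is not None:
        col = fig.table.annotation(fig_layer.variable)
        if col.kind == CONTINUOUS:
            cmap = continuous_cmap(fig_layer.palette or style.get("continuous_cmap"))
            face = _continuous_fill_colors(col, cmap, missing_color)
        else:
            cmap = discrete_colors(
                col.levels, fig_layer.palette or style.get("discrete_palette")
            )
            face = [
                missing_color if m else cmap[str(v)]
                for v, m in zip(col.values, col.missing)
            ]
            handles.extend(
                Patch(facecolor=c, edgecolor="none", label=f"{fig_layer.variable}: {lev}")
                for lev, c in cmap.items()
            )

    grd = fig.layer("ground")
    if grd is not None:
        col = fig.table.annotation(grd.variable)
        cmap = discrete_colors(col.levels, grd.palette or style.get("discrete_palette"))
        edge = [
            missing_color if m else cmap[str(v)]
            for v, m in zip(col.values, col.missing)
        ]
        handles.extend(
            Patch(facecolor="none", edgecolor=c, label=f"{grd.variable}: {lev}")
            for lev, c in cmap.items()
        )
    return face, edge, handles


def _points_per_data_unit(mplfig, ax) -> float:
    """Conversion factor for expressing a data-unit stroke in points."""
    (x0, x1), pos = ax.get_xlim(), ax.get_position()
    axis_pt = pos.width * mplfig.get_size_inches()[0] * 72.0
    return axis_pt / abs(x1 - x0)


def render(fig: FigureSpec, path: str | Path, format: str | None = None) -> Path:
    """Render the layer stack to ``path`` (png, pdf, or svg).

    Spots are drawn in ascending point-id order so overlaps are
    deterministic; symbol glyphs are always emitted after every disc.
    In SVG output each disc carries a ``spot-<id>`` gid and each glyph
    group a ``symbol-<level>`` gid, so stroke/fill assignment and
    z-order are textually checkable.
    """
    if not fig.layers:
        raise ValidationError("cannot render a figure with zero layers")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "png").lower()
    if fmt not in ("png", "pdf", "svg"):
        raise ValidationError(f"unsupported format {fmt!r}")

    style = StyleConfig()  # per-call styles resolved in layer specs
    table = fig.table
    dpi = 100.0
    mplfig = Figure(
        figsize=(fig.width_px / dpi, fig.height_px / dpi), dpi=dpi
    )
    mplfig.patch.set_facecolor(fig.background)
    ax = mplfig.add_subplot(111)
    ax.set_facecolor(fig.background)
    ax.set_aspect("equal", adjustable="box")

    r = fig.spot_diameter / 2.0
    pad = fig.spot_diameter * 1.5
    ax.set_xlim(table.x.min() - pad, table.x.max() + pad)
    if table.coord_mode == "image":
        ax.set_ylim(table.y.max() + pad, table.y.min() - pad)  # y down
    else:
        ax.set_ylim(table.y.min() - pad, table.y.max() + pad)
    ax.set_xticks([])
    ax.set_yticks([])
    for s in ax.spines.values():
        s.set_visible(False)
    if fig.title:
        ax.set_title(fig.title)

    face, edge, handles = _resolve_spot_paints(fig, style)
    grd = fig.layer("ground")
    stroke_data = (
        grd.stroke_width
        if grd is not None and grd.stroke_width is not None
        else DEFAULT_STROKE_FRAC * fig.spot_diameter
    )
    lw = stroke_data * _points_per_data_unit(mplfig, ax)

    order = np.argsort(np.array([str(i) for i in table.point_ids], dtype=object))
    for i in order:
        pid = str(table.point_ids[i])
        patch = Circle(
            (table.x[i], table.y[i]),
            radius=r,
            facecolor=face[i],
            edgecolor=edge[i],
            linewidth=lw if edge[i] != "none" else 0.0,
            zorder=2,
        )
        patch.set_gid(f"spot-{pid}")
        # add_artist, not add_patch: limits are already set and per-patch
        # data-limit updates dominate run time for thousands of spots
        ax.add_artist(patch)

    sym = fig.layer("symbol")
    if sym is not None:
        col = table.annotation(sym.variable)
        sym_color = style.get("symbol_color", "black")
        for lev in sorted(sym.glyph_map):
            marker = GLYPHS[sym.glyph_map[lev]]
            mask = np.array(
                [(not m) and str(v) == lev for v, m in zip(col.values, col.missing)]
            )
            if not mask.any():
                continue
            (line,) = ax.plot(
                table.x[mask],
                table.y[mask],
                linestyle="none",
                marker=marker,
                markersize=max(2.0, r * _points_per_data_unit(mplfig, ax)),
                markeredgewidth=lw,
                color=sym_color,
                zorder=3,
            )
            line.set_gid(f"symbol-{lev}")
            handles.append(
                Line2D(
                    [], [], linestyle="none", marker=marker, color=sym_color,
                    label=f"{sym.variable}: {lev}",
                )
            )

    if fig.show_legend and handles:
        ax.legend(
            handles=handles, loc="center left", bbox_to_anchor=(1.0, 0.5),
            frameon=False, fontsize=8,
        )

    try:
        # keep SVG text as <text> (not glyph paths) so legends are
        # textually checkable; drop the date stamp for reproducible bytes
        kw = {"metadata": {"Date": None}} if fmt == "svg" else {}
        with matplotlib.rc_context({"svg.fonttype": "none", "svg.hashsalt": "spotglass"}):
            mplfig.savefig(path, format=fmt, bbox_inches="tight", **kw)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path
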