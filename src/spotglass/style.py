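"""Palettes and flat TOML style configuration.

Categorical levels get deterministic colors: levels are sorted and
assigned round-robin from a colorblind-safe cycle (Okabe-Ito), so the
same data always renders with the same colors regardless of row order.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import matplotlib as mpl
from matplotlib.colors import to_hex

__all__ = ["OKABE_ITO", "discrete_colors", "continuous_cmap", "StyleConfig", "load_style"]

#: Okabe-Ito colorblind-safe cycle (without black, reserved for symbols).
OKABE_ITO = [
    "#e69f00",  # orange
    "#56b4e9",  # sky blue
    "#009e73",  # bluish green
    "#f0e442",  # yellow
    "#0072b2",  # blue
    "#d55e00",  # vermillion
    "#cc79a7",  # reddish purple
    "#999999",  # grey
]

_NAMED_PALETTES = {"okabe-ito": OKABE_ITO}


def discrete_colors(levels: list[str], palette=None) -> dict[str, str]:
    """Map sorted levels to hex colors.

    ``palette`` may be a named discrete palette, an explicit color list,
    or the name of a matplotlib colormap to sample; default Okabe-Ito.
    More levels than colors wraps around the cycle.
    """
    levels = sorted(levels)
    if palette is None:
        cycle = OKABE_ITO
    elif isinstance(palette, str):
        if palette in _NAMED_PALETTES:
            cycle = _NAMED_PALETTES[palette]
        else:
            cmap = mpl.colormaps[palette]
            n = max(len(levels), 1)
            return {
                lev: to_hex(cmap(i / max(n - 1, 1))) for i, lev in enumerate(levels)
            }
    else:
        cycle = [to_hex(c) for c in palette]
    return {lev: cycle[i % len(cycle)] for i, lev in enumerate(levels)}


def continuous_cmap(palette=None):
    """Resolve a continuous colormap id (default viridis)."""
    return mpl.colormaps[palette or "viridis"]


class StyleConfig(dict):
    """Flat key-value style defaults (stroke fraction, dimensions, palettes).

    Recognized keys: ``stroke_frac``, ``width_px``, ``height_px``,
    ``background``, ``continuous_cmap``, ``discrete_palette``,
    ``missing_color``, ``symbol_color``.
    """

    def get_num(self, key: str, default: float) -> float:
        return float(self.get(key, default))


def load_style(path: str | Path | None) -> StyleConfig:
    """Load a flat TOML style file; ``None`` gives all defaults."""
    if path is None:
        return StyleConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    flat = {k: v for k, v in data.items() if not isinstance(v, dict)}
    # allow one level of nesting under [style] for tidiness
    flat.update(data.get("style", {}))
    return StyleConfig(flat)
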