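"""Activity-map rendering and per-cell expression plots.

All figures use the Agg backend conventions: image coordinates (origin
top-left, y downward), one filled rectangle per significant window coloured
by the chosen value field, and an optional contour tracing the boundary of
the union of all cell-containing leaf windows — a cheap tissue outline that
needs no raster segmentation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.patches import Rectangle
from shapely.geometry import box
from shapely.ops import unary_union

from .core import ConfigError, intensity_col

__all__ = ["render_activity_map", "plot_marker_expression", "tissue_contour"]

VALUE_FIELDS = ("neg_log10_p", "percentile", "minmax_score")


def tissue_contour(windows: pd.DataFrame):
    """Union of all leaf-window rectangles as a shapely (Multi)Polygon."""
    boxes = [
        box(r.x0, r.y0, r.x1, r.y1)
        for r in windows.itertuples()
        if r.n_total_cells > 0
    ]
    if not boxes:
        return None
    return unary_union(boxes)


def _draw_polygon(ax, geom, **kwargs):
    geoms = getattr(geom, "geoms", [geom])
    for g in geoms:
        xs, ys = g.exterior.xy
        ax.plot(xs, ys, **kwargs)
        for ring in g.interiors:
            xs, ys = ring.xy
            ax.plot(xs, ys, **kwargs)


def render_activity_map(
    windows: pd.DataFrame,
    value_field: str = "neg_log10_p",
    cmap: str = "inferno",
    background: str | None = None,
    contour: bool = True,
    dim_nonsignificant: bool = False,
    out=None,
    ax=None,
):
    """Render the per-window significance heatmap.

    Parameters
    ----------
    windows
        Result table from :class:`~lrscan.model.LocalCoexpressionResults`
        (needs the window bounds, ``significant`` and *value_field*).
    value_field
        Column colouring the rectangles: ``neg_log10_p``, ``percentile`` or
        ``minmax_score``.
    background
        Optional raster image path drawn under the map.
    contour
        Draw the boundary of the union of cell-containing leaf windows.
    dim_nonsignificant
        Draw non-significant windows faintly instead of omitting them.
    out
        Path to save a PNG; when ``None`` the axes object is returned
        without saving.
    """
    if value_field not in windows.columns:
        raise ConfigError(
            f"unknown value field {value_field!r}; expected one of {VALUE_FIELDS}"
        )
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(7, 7))
    else:
        fig = ax.figure

    if background is not None:
        img = plt.imread(background)
        ax.imshow(img, origin="upper")

    vmax = float(windows[value_field].max()) if len(windows) else 1.0
    vmax = vmax if vmax > 0 else 1.0
    cm = plt.get_cmap(cmap)

    sig = windows.loc[windows["significant"]] if "significant" in windows else windows
    patches = [
        Rectangle((r.x0, r.y0), r.x1 - r.x0, r.y1 - r.y0) for r in sig.itertuples()
    ]
    colors = [cm(v / vmax) for v in sig[value_field]]
    ax.add_collection(PatchCollection(patches, facecolor=colors, edgecolor="none"))

    if dim_nonsignificant and "significant" in windows:
        rest = windows.loc[~windows["significant"]]
        dim_patches = [
            Rectangle((r.x0, r.y0), r.x1 - r.x0, r.y1 - r.y0) for r in rest.itertuples()
        ]
        ax.add_collection(
            PatchCollection(dim_patches, facecolor="0.9", edgecolor="none", alpha=0.5)
        )

    if contour:
        geom = tissue_contour(windows)
        if geom is not None:
            _draw_polygon(ax, geom, color="0.3", linewidth=0.8)

    if len(windows):
        ax.set_xlim(windows["x0"].min(), windows["x1"].max())
        ax.set_ylim(windows["y0"].min(), windows["y1"].max())
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"L-R activity map ({value_field})")
    sm = plt.cm.ScalarMappable(cmap=cm, norm=plt.Normalize(0, vmax))
    fig.colorbar(sm, ax=ax, shrink=0.8, label=value_field)

    if out is not None:
        fig.savefig(out, dpi=150)
        if own_fig:
            plt.close(fig)
    return ax


def plot_marker_expression(cells: pd.DataFrame, marker: str, out=None, cmap="viridis", ax=None):
    """Scatter of cell centroids coloured by (clipped) marker intensity."""
    col = intensity_col(marker)
    if col not in cells.columns:
        raise ConfigError(f"unknown marker {marker!r}")
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(7, 7))
    else:
        fig = ax.figure
    sc = ax.scatter(
        cells["x"], cells["y"], c=cells[col], s=4, cmap=cmap, linewidths=0
    )
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{marker} expression")
    if len(cells):
        fig.colorbar(sc, ax=ax, shrink=0.8, label="mean intensity")
    if out is not None:
        fig.savefig(out, dpi=150)
        if own_fig:
            plt.close(fig)
    return ax
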