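"""Adaptive window scanning.

The tissue is covered by an initial grid of large windows; any window holding
more cells than ``cell_count_threshold`` is replaced by a grid of smaller
children (edges ``subset_rate`` times the parent's, quadrants at the default
50%), and any window holding fewer than ``min_cells`` cells is discarded.
The procedure terminates because every split strictly shrinks the edges; a
window that still exceeds the threshold once its edge reaches
``min_window_edge`` (e.g. many cells sharing one centroid) is retained as a
flagged *forced* leaf instead of being split forever.

Retained leaves are pairwise disjoint half-open rectangles, so every cell is
counted in at most one leaf; cells in discarded windows are the only losses.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import ConfigError, MarkerPanel, ScanConfig, Window, WindowSet, positive_col

__all__ = ["init_windows", "scan_windows"]


def _axis_edges(length: float, step: float) -> list[tuple[float, float]]:
    """Half-open intervals of width *step* tiling [0, length), last truncated."""
    n = max(1, math.ceil(length / step - 1e-9))
    out = []
    for i in range(n):
        lo = i * step
        hi = min(length, (i + 1) * step)
        if hi > lo:
            out.append((lo, hi))
    return out


def init_windows(
    image_extent: tuple[float, float], cfg: ScanConfig
) -> list[tuple[float, float, float, float]]:
    """Initial depth-0 grid of window bounds tiling the image exactly.

    Each window has edge ``init_rate`` times the corresponding image
    dimension; the last row/column is truncated at the image border so the
    union reproduces the image rectangle.
    """
    width, height = float(image_extent[0]), float(image_extent[1])
    if width <= 0 or height <= 0:
        raise ConfigError("image extent must be positive")
    if cfg.init_rate * min(width, height) < 1.0:
        raise ConfigError("init_rate times the image extent is below one pixel")
    xs = _axis_edges(width, cfg.init_rate * width)
    ys = _axis_edges(height, cfg.init_rate * height)
    return [(x0, y0, x1, y1) for (y0, y1) in ys for (x0, x1) in xs]


def _children(
    x0: float, y0: float, x1: float, y1: float, subset_rate: float
) -> list[tuple[float, float, float, float]]:
    """Disjoint child grid with edges subset_rate x the parent edges.

    For subset_rate = 0.5 these are the four quadrants; for rates that do not
    divide the parent evenly the last row/column is truncated at the parent
    boundary so children always tile the parent.
    """
    out = []
    for cy0, cy1 in _axis_edges(y1 - y0, subset_rate * (y1 - y0)):
        for cx0, cx1 in _axis_edges(x1 - x0, subset_rate * (x1 - x0)):
            out.append((x0 + cx0, y0 + cy0, x0 + cx1, y0 + cy1))
    return out


def scan_windows(
    cells: pd.DataFrame,
    image_extent: tuple[float, float],
    cfg: ScanConfig,
    panel: MarkerPanel,
    reference_round: str | None = None,
) -> WindowSet:
    """Run the recursive scan and return the retained leaf windows.

    Parameters
    ----------
    cells
        Validated cell table with positivity columns for every panel marker.
    image_extent
        ``(width, height)`` of the scanned image in pixels.
    reference_round
        When cells from several registered imaging rounds are pooled, the
        split/discard decisions and the total-cell denominators use only the
        cells of this round (the round whose nuclear stain defines "a cell"),
        while per-marker positive counts use whichever round carries the
        marker.  ``None`` counts every cell.

    Returns
    -------
    WindowSet
        Leaves with per-marker positive counts, plus the number of windows
        discarded for holding fewer than ``min_cells`` cells, the number of
        forced leaves, and the number of cells lost to discarded windows.
    """
    for m in panel.markers:
        if positive_col(m) not in cells.columns:
            raise ConfigError(f"missing positivity column for marker {m!r}; run QC first")

    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    if reference_round is None:
        is_ref = np.ones(len(cells), dtype=bool)
    else:
        is_ref = (cells["round_id"] == reference_round).to_numpy()
    pos = {m: cells[positive_col(m)].to_numpy(dtype=bool) for m in panel.markers}

    leaves: list[Window] = []
    discarded = 0
    discarded_cells = 0
    forced = 0

    # worklist of (bounds, depth, candidate cell indices)
    all_idx = np.arange(len(cells))
    stack: list[tuple[tuple[float, float, float, float], int, np.ndarray]] = [
        (b, 0, all_idx) for b in init_windows(image_extent, cfg)
    ]
    while stack:
        (x0, y0, x1, y1), depth, cand = stack.pop()
        inside = cand[(x[cand] >= x0) & (x[cand] < x1) & (y[cand] >= y0) & (y[cand] < y1)]
        n_ref = int(is_ref[inside].sum())
        if n_ref < cfg.min_cells:
            discarded += 1
            discarded_cells += n_ref
            continue
        splittable = min(x1 - x0, y1 - y0) > cfg.min_window_edge
        if n_ref > cfg.cell_count_threshold and splittable:
            for child in _children(x0, y0, x1, y1, cfg.subset_rate):
                stack.append((child, depth + 1, inside))
            continue
        is_forced = n_ref > cfg.cell_count_threshold
        forced += int(is_forced)
        counts = {m: int(pos[m][inside].sum()) for m in panel.markers}
        leaves.append(
            Window(
                window_id=f"w{len(leaves):05d}",
                x0=x0,
                y0=y0,
                x1=x1,
                y1=y1,
                depth=depth,
                n_total_cells=n_ref,
                marker_counts=counts,
                forced=is_forced,
            )
        )

    # Deterministic spatial order regardless of worklist traversal order.
    leaves.sort(key=lambda w: (w.y0, w.x0))
    leaves = [
        Window(
            window_id=f"w{i:05d}",
            x0=w.x0,
            y0=w.y0,
            x1=w.x1,
            y1=w.y1,
            depth=w.depth,
            n_total_cells=w.n_total_cells,
            marker_counts=w.marker_counts,
            forced=w.forced,
        )
        for i, w in enumerate(leaves)
    ]
    return WindowSet(
        leaves=leaves,
        discarded_count=discarded,
        forced_count=forced,
        discarded_cells=discarded_cells,
        image_extent=(float(image_extent[0]), float(image_extent[1])),
    )
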