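"""Independent brute-force oracles the implementation is checked against.

Deliberately naive: plain recursion, python double loops and exhaustive
searches, sharing no code path with the package internals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def _tiles(length: float, step: float) -> list[tuple[float, float]]:
    n = max(1, math.ceil(length / step - 1e-9))
    return [(i * step, min(length, (i + 1) * step)) for i in range(n) if min(length, (i + 1) * step) > i * step]


def quadtree_leaves(
    cells: pd.DataFrame, extent, cfg, markers
) -> tuple[set, int, int, int]:
    """Recursive reference enumeration of the adaptive scan.

    Returns (leaf set, n_discarded, n_forced, n_discarded_cells); each leaf is
    a tuple (bounds rounded to 6 dp, depth, n_total, per-marker counts, forced).
    """
    width, height = float(extent[0]), float(extent[1])
    leaves: set = set()
    stats = {"disc": 0, "forced": 0, "lost": 0}

    def recurse(x0, y0, x1, y1, depth, df):
        sub = df[(df["x"] >= x0) & (df["x"] < x1) & (df["y"] >= y0) & (df["y"] < y1)]
        n = len(sub)
        if n < cfg.min_cells:
            stats["disc"] += 1
            stats["lost"] += n
            return
        if n <= cfg.cell_count_threshold or min(x1 - x0, y1 - y0) <= cfg.min_window_edge:
            forced = n > cfg.cell_count_threshold
            stats["forced"] += int(forced)
            counts = tuple(int(sub[f"{m}_positive"].sum()) for m in markers)
            leaves.add(
                (
                    round(x0, 6),
                    round(y0, 6),
                    round(x1, 6),
                    round(y1, 6),
                    depth,
                    n,
                    counts,
                    forced,
                )
            )
            return
        for cy0, cy1 in _tiles(y1 - y0, cfg.subset_rate * (y1 - y0)):
            for cx0, cx1 in _tiles(x1 - x0, cfg.subset_rate * (x1 - x0)):
                recurse(x0 + cx0, y0 + cy0, x0 + cx1, y0 + cy1, depth + 1, sub)

    for gy0, gy1 in _tiles(height, cfg.init_rate * height):
        for gx0, gx1 in _tiles(width, cfg.init_rate * width):
            recurse(gx0, gy0, gx1, gy1, 0, cells)
    return leaves, stats["disc"], stats["forced"], stats["lost"]


def windowset_as_leafset(ws) -> set:
    """Project a WindowSet onto the oracle's leaf-tuple representation."""
    out = set()
    for w in ws.leaves:
        out.add(
            (
                round(w.x0, 6),
                round(w.y0, 6),
                round(w.x1, 6),
                round(w.y1, 6),
                w.depth,
                w.n_total_cells,
                tuple(w.marker_counts.values()),
                w.forced,
            )
        )
    return out


def pair_score(n_a: int, n_b: int, n_total: int) -> float:
    if n_a == 0 or n_b == 0:
        return 0.0
    return (n_a + n_b) / n_total


def significance_bruteforce(scores: pd.DataFrame, target_col: str = "target_lr") -> pd.DataFrame:
    """Double-loop recomputation of the merged-background empirical test."""
    target = scores[target_col]
    bg_cols = [c for c in scores.columns if c != target_col]
    rows = []
    for wid in scores.index:
        s = target[wid]
        if s <= 0:
            rows.append((wid, 0, 0, 0.0, 1.0))
            continue
        background = [scores.at[wid, c] for c in bg_cols]
        background += [
            target[o] for o in scores.index if o != wid and target[o] > 0
        ]
        nb = sum(1 for b in background if s >= b)
        m = len(background)
        rows.append((wid, m, nb, nb / m if m else 0.0, (m - nb + 1) / (m + 1) if m else 1.0))
    return pd.DataFrame(
        rows, columns=["window_id", "background_size", "n_beaten", "percentile", "p_value"]
    ).set_index("window_id")


def percentile_lower(values, q: float) -> float:
    """Nearest-lower order statistic percentile from first principles."""
    a = sorted(float(v) for v in values)
    return a[math.floor((len(a) - 1) * q / 100.0)]


def otsu_bruteforce(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over histogram split points maximising the
    between-class variance; returns the threshold (bin centre)."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, centers[0]
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k - 1]
    return float(best_thr)
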