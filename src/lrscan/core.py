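"""Shared data types for cells, marker panels, windows, transforms and results.

Conventions used throughout the package:

* Cell centroids are continuous pixel coordinates with the image origin at the
  top-left corner, x increasing rightward and y increasing downward.
* A window is the half-open rectangle ``[x0, x1) x [y0, y1)``; a cell belongs
  to a window iff its centroid lies inside.  Half-open membership makes sibling
  windows disjoint, so per-window cell counts are well defined.
* Cell tables are plain :class:`pandas.DataFrame` objects with one row per
  segmented cell.  Required columns: ``cell_id``, ``x``, ``y``, ``area``;
  marker intensities live in ``<marker>_mean`` columns, positivity calls in
  ``<marker>_positive`` columns, and the imaging round in ``round_id``
  (default ``"r1"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ConfigError",
    "EstimationError",
    "MarkerPanel",
    "ScanConfig",
    "QCConfig",
    "GateSpec",
    "Window",
    "WindowSet",
    "TransformParams",
    "intensity_col",
    "positive_col",
    "validate_cell_table",
    "read_cell_table",
    "write_cell_table",
    "write_windows_csv",
    "windows_to_geojson",
]

DEFAULT_ROUND = "r1"


class SchemaError(ValueError):
    """A cell table is missing columns or violates per-cell invariants."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


class EstimationError(RuntimeError):
    """A transform could not be estimated from the given point sets."""


def intensity_col(marker: str) -> str:
    return f"{marker}_mean"


def positive_col(marker: str) -> str:
    return f"{marker}_positive"


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel with the target ligand-receptor pair.

    Parameters
    ----------
    markers
        Marker names, in panel order.  The order fixes the deterministic
        enumeration order of background (non-interacting) marker pairs.
    target_ligand, target_receptor
        The L-R pair whose local co-expression is being mapped.  Both must
        be panel members and must differ.
    known_lr_pairs
        Additional marker pairs known to interact; these are excluded from
        the random-pair null alongside the target pair.
    """

    markers: tuple[str, ...]
    target_ligand: str
    target_receptor: str
    known_lr_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        object.__setattr__(
            self, "known_lr_pairs", tuple(tuple(p) for p in self.known_lr_pairs)
        )
        if len(markers) < 2:
            raise ConfigError("a marker panel needs at least 2 markers")
        if any(not isinstance(m, str) or not m for m in markers):
            raise ConfigError("marker names must be non-empty strings")
        if len(set(markers)) != len(markers):
            raise ConfigError("marker names must be unique")
        if self.target_ligand == self.target_receptor:
            raise ConfigError("target ligand and receptor must differ")
        for m in (self.target_ligand, self.target_receptor):
            if m not in markers:
                raise ConfigError(f"target marker {m!r} is not in the panel")
        for a, b in self.known_lr_pairs:
            if a not in markers or b not in markers:
                raise ConfigError(f"known L-R pair ({a!r}, {b!r}) not in the panel")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def target_pair(self) -> frozenset[str]:
        return frozenset((self.target_ligand, self.target_receptor))


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the recursive window scan.

    ``cell_count_threshold`` is the largest cell count a retained window may
    have (windows above it are subdivided); ``min_cells`` the smallest
    (windows below it are discarded).  ``init_rate`` sets the initial grid
    window edge as a fraction of the image extent, ``subset_rate`` the child
    window edge as a fraction of its parent (0.5 = quadrants), and
    ``min_window_edge`` is the recursion floor in pixels below which an
    over-full window is retained as a flagged "forced" leaf instead of being
    split further.
    """

    cell_count_threshold: int = 100
    min_cells: int = 2
    subset_rate: float = 0.5
    init_rate: float = 0.125
    min_window_edge: float = 16.0

    def __post_init__(self) -> None:
        if not (0.0 < self.subset_rate < 1.0):
            raise ConfigError("subset_rate must be in (0, 1)")
        if not (0.0 < self.init_rate <= 1.0):
            raise ConfigError("init_rate must be in (0, 1]")
        if self.min_cells < 2:
            raise ConfigError("min_cells must be >= 2")
        if self.cell_count_threshold <= self.min_cells:
            raise ConfigError("cell_count_threshold must exceed min_cells")
        if self.min_window_edge <= 0:
            raise ConfigError("min_window_edge must be positive")


@dataclass(frozen=True)
class GateSpec:
    """Positivity gate for one marker.

    method ``"manual"`` uses ``value`` as an absolute intensity threshold;
    ``"quantile"`` gates above the ``value``-quantile of that marker over all
    cells; ``"otsu"`` uses the two-class variance-maximising threshold on a
    256-bin histogram of the marker.
    """

    method: str = "otsu"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("manual", "quantile", "otsu"):
            raise ConfigError(f"unknown gating method {self.method!r}")
        if self.method == "manual" and self.value is None:
            raise ConfigError("manual gating requires a threshold value")
        if self.method == "quantile":
            if self.value is None or not (0.0 < self.value < 1.0):
                raise ConfigError("quantile gating requires q in (0, 1)")


@dataclass(frozen=True)
class QCConfig:
    """Quality-control parameters: clipping, area filtering and gating."""

    clip_percentile: float = 95.0
    area_percentile: float = 5.0
    gates: dict[str, GateSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_percentile <= 100.0):
            raise ConfigError("clip_percentile must be in (0, 100]")
        if not (0.0 <= self.area_percentile < 100.0):
            raise ConfigError("area_percentile must be in [0, 100)")


@dataclass(frozen=True)
class Window:
    """One leaf rectangle of the scan with its per-marker positive counts."""

    window_id: str
    x0: float
    y0: float
    x1: float
    y1: float
    depth: int
    n_total_cells: int
    marker_counts: dict[str, int]
    forced: bool = False

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("window bounds must satisfy x0 < x1 and y0 < y1")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0


@dataclass
class WindowSet:
    """Leaf windows retained by the scan plus bookkeeping counts."""

    leaves: list[Window]
    discarded_count: int
    forced_count: int
    discarded_cells: int
    image_extent: tuple[float, float]

    def __len__(self) -> int:
        return len(self.leaves)

    def to_frame(self) -> pd.DataFrame:
        """One row per leaf: bounds, depth, total and per-marker counts."""
        rows = []
        for w in self.leaves:
            row = {
                "window_id": w.window_id,
                "x0": w.x0,
                "y0": w.y0,
                "x1": w.x1,
                "y1": w.y1,
                "depth": w.depth,
                "forced": w.forced,
                "n_total_cells": w.n_total_cells,
            }
            for m, c in w.marker_counts.items():
                row[f"n_pos_{m}"] = c
            rows.append(row)
        cols = ["window_id", "x0", "y0", "x1", "y1", "depth", "forced", "n_total_cells"]
        if rows:
            cols += [k for k in rows[0] if k.startswith("n_pos_")]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class TransformParams:
    """A 2-D linear-plus-offset coordinate transform ``p -> A p + t``."""

    kind: str
    matrix: tuple[tuple[float, float], tuple[float, float]]
    offset: tuple[float, float]
    residual: float = float("nan")

    _KINDS = ("translation", "rigid", "similarity", "affine")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigError(f"unknown transform kind {self.kind!r}")
        a = np.asarray(self.matrix, dtype=float)
        if a.shape != (2, 2):
            raise ConfigError("matrix must be 2x2")
        if abs(np.linalg.det(a)) < 1e-12:
            raise ConfigError("transform linear part must be invertible")
        if self.kind in ("rigid", "similarity"):
            # scaled rotation: A^T A = s^2 I
            ata = a.T @ a
            s2 = ata[0, 0]
            if not np.allclose(ata, s2 * np.eye(2), atol=1e-6 * max(1.0, s2)):
                raise ConfigError(f"{self.kind} transform must be a (scaled) rotation")
        object.__setattr__(self, "matrix", tuple(tuple(float(v) for v in r) for r in a))
        object.__setattr__(self, "offset", tuple(float(v) for v in self.offset))

    @classmethod
    def identity(cls, kind: str = "rigid") -> "TransformParams":
        return cls(kind=kind, matrix=((1.0, 0.0), (0.0, 1.0)), offset=(0.0, 0.0), residual=0.0)

    @property
    def A(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.offset, dtype=float)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.A.T + self.t

    def inverse(self) -> "TransformParams":
        ainv = np.linalg.inv(self.A)
        return TransformParams(
            kind=self.kind,
            matrix=tuple(map(tuple, ainv)),
            offset=tuple(-ainv @ self.t),
            residual=self.residual,
        )

    def with_residual(self, residual: float) -> "TransformParams":
        return replace(self, residual=float(residual))


# ---------------------------------------------------------------------------
# Cell-table validation and I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("cell_id", "x", "y", "area")


def validate_cell_table(raw: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Validate a raw per-cell measurement table against a marker panel.

    Checks the required schema (``cell_id, x, y, area`` plus one
    ``<marker>_mean`` intensity column per panel marker), uniqueness of cell
    ids, finiteness of coordinates and non-negativity of areas/intensities,
    and returns a copy with normalised column order.  A positivity column,
    where present, must carry a call for every cell; it is coerced to bool.

    Raises
    ------
    SchemaError
        on a missing column, duplicate ``cell_id``, or invalid values.
    """
    df = pd.DataFrame(raw).copy()
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    for m in panel.markers:
        if intensity_col(m) not in df.columns:
            raise SchemaError(f"cell table is missing intensity column {intensity_col(m)!r}")
    if "round_id" not in df.columns:
        df["round_id"] = DEFAULT_ROUND

    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SchemaError(f"duplicate cell_id {dup!r}")

    for col in ("x", "y", "area"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if len(df):
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise SchemaError("cell centroids must be finite")
        if not (df["area"] > 0).all():
            raise SchemaError("cell areas must be positive")

    for m in panel.markers:
        col = intensity_col(m)
        vals = pd.to_numeric(df[col], errors="raise").astype(float)
        present = vals.notna()
        if len(df) and (vals[present] < 0).any():
            raise SchemaError(f"negative intensity in column {col!r}")
        df[col] = vals

    pos_cols = [positive_col(m) for m in panel.markers if positive_col(m) in df.columns]
    for col in pos_cols:
        if df[col].isna().any():
            raise SchemaError(f"positivity column {col!r} has missing values")
        df[col] = df[col].astype(bool)

    ordered = list(_REQUIRED) + ["round_id"]
    ordered += [intensity_col(m) for m in panel.markers]
    ordered += pos_cols
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra].reset_index(drop=True)


def read_cell_table(path, panel: MarkerPanel, sep: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV cell table and validate it against *panel*."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_cell_table(pd.read_csv(path, sep=sep), panel)


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_windows_csv(results: pd.DataFrame, path) -> None:
    """Write the per-window result table (bounds, counts, score, p) to CSV."""
    results.to_csv(path, index=False)


def windows_to_geojson(results: pd.DataFrame) -> dict:
    """Per-window rectangles as a GeoJSON FeatureCollection for overlay tools."""
    feats = []
    prop_cols = [c for c in results.columns if c not in ("x0", "y0", "x1", "y1")]
    for _, r in results.iterrows():
        ring = [
            [r["x0"], r["y0"]],
            [r["x1"], r["y0"]],
            [r["x1"], r["y1"]],
            [r["x0"], r["y1"]],
            [r["x0"], r["y0"]],
        ]
        props = {}
        for c in prop_cols:
            v = r[c]
            props[c] = v.item() if hasattr(v, "item") else v
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}
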