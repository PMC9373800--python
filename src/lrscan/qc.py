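"""Per-cell quality control: Z-slice aggregation, clipping, area filtering,
and positive-cell calling.

The QC chain runs in the order the measurements arrive from the microscope:
per-Z-slice intensities are averaged into one scalar per cell and marker,
bright outliers are clipped to an upper percentile, implausibly small cells
(segmentation debris) are dropped, and finally each marker is gated into
positive/negative calls.

Percentile convention: the clip cap and the area cut use the nearest-lower
order statistic (``numpy method="lower"``) rather than linear interpolation.
The cap is then itself an observed value, which makes clipping exactly
idempotent — re-clipping a clipped table is a no-op because the cap is
reproduced from the tied values it created.  An interpolated cap drifts
downward on every reapplication.  Quantile *gating* keeps numpy's default
interpolated quantile, where no such fixed-point property is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import (
    ConfigError,
    GateSpec,
    MarkerPanel,
    QCConfig,
    SchemaError,
    intensity_col,
    positive_col,
)

__all__ = [
    "aggregate_z_slices",
    "clip_intensities",
    "filter_cells_by_area",
    "call_positive_cells",
    "apply_qc",
]


def aggregate_z_slices(df: pd.DataFrame, markers: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Average per-Z-slice intensities into one ``<marker>_mean`` per cell.

    Expects columns ``<marker>_z<k>`` (k = 1..n_slides) holding the mean
    signal of the cell in each Z-slice; the aggregate is their arithmetic
    mean.  All cells must share the same slice count per marker — a missing
    value in any slice column is treated as a ragged stack and rejected.
    """
    out = df.copy()
    for m in markers:
        slice_cols = sorted(
            (c for c in df.columns if c.startswith(f"{m}_z") and c[len(m) + 2 :].isdigit()),
            key=lambda c: int(c[len(m) + 2 :]),
        )
        if not slice_cols:
            if intensity_col(m) in df.columns:
                continue
            raise SchemaError(f"no Z-slice or mean intensity columns for marker {m!r}")
        block = out[slice_cols].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise SchemaError(f"ragged Z-stack for marker {m!r}: missing slice values")
        out[intensity_col(m)] = block.mean(axis=1)
    return out


def clip_intensities(cells: pd.DataFrame, cfg: QCConfig, panel: MarkerPanel) -> pd.DataFrame:
    """Clip each marker's intensities to its upper ``clip_percentile``.

    The cap is computed per marker over all cells as the nearest-lower order
    statistic (see module docstring); values above it are set to it,
    everything else is left untouched.  Exactly idempotent.
    """
    out = cells.copy()
    if not len(out):
        return out
    for m in panel.markers:
        col = intensity_col(m)
        vals = out[col].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError(f"non-finite intensity in column {col!r}")
        if np.isnan(vals).all():
            continue  # marker not measured in any pooled round
        cap = np.nanpercentile(vals, cfg.clip_percentile, method="lower")
        out[col] = np.where(vals > cap, cap, vals)  # NaN (unmeasured round) passes through
    return out


def filter_cells_by_area(cells: pd.DataFrame, cfg: QCConfig) -> pd.DataFrame:
    """Drop cells whose area is strictly below the ``area_percentile`` cut.

    Small detections are usually segmentation debris rather than nuclei.
    Cells exactly at the percentile survive, so constant-area tables are
    never filtered; survivor order is preserved.
    """
    if "area" not in cells.columns:
        raise SchemaError("cell table is missing required column 'area'")
    if not len(cells):
        return cells.copy()
    cut = np.percentile(cells["area"].to_numpy(dtype=float), cfg.area_percentile, method="lower")
    return cells.loc[cells["area"] >= cut].reset_index(drop=True)


def _gate_threshold(vals: np.ndarray, gate: GateSpec) -> float:
    """Threshold from the finite (measured) intensities only."""
    if gate.method == "manual":
        return float(gate.value)
    finite = vals[np.isfinite(vals)]
    if not finite.size:
        return float("inf")  # marker unmeasured: nothing can be positive
    if gate.method == "quantile":
        return float(np.quantile(finite, gate.value))
    # Otsu on a 256-bin histogram over the observed range.
    if np.ptp(finite) == 0:
        return float(finite[0])  # constant signal: nothing exceeds it
    return float(threshold_otsu(finite, nbins=256))


def call_positive_cells(
    cells: pd.DataFrame, cfg: QCConfig, panel: MarkerPanel
) -> pd.DataFrame:
    """Gate each marker into boolean positive/negative calls.

    A cell is positive for a marker iff its (clipped) intensity is strictly
    above the gate threshold.  Gates default to Otsu when a marker has no
    entry in ``cfg.gates``, but the target ligand and receptor must be gated
    explicitly — silent defaults on the pair under test are refused.

    Clustering-based phenotyping can be substituted by supplying
    ``<marker>_positive`` columns up front (see
    :func:`lrscan.core.validate_cell_table`); this function overwrites them.
    """
    for m in (panel.target_ligand, panel.target_receptor):
        if m not in cfg.gates:
            raise ConfigError(
                f"no gate configured for target marker {m!r}; "
                "set qc.gates for the ligand and receptor explicitly"
            )
    out = cells.copy()
    for m in panel.markers:
        gate = cfg.gates.get(m, GateSpec(method="otsu"))
        vals = out[intensity_col(m)].to_numpy(dtype=float)
        if not len(vals):
            out[positive_col(m)] = pd.Series([], dtype=bool)
            continue
        thr = _gate_threshold(vals, gate)
        out[positive_col(m)] = vals > thr
    return out


def apply_qc(cells: pd.DataFrame, cfg: QCConfig, panel: MarkerPanel) -> pd.DataFrame:
    """Full QC chain: clip, area-filter, then gate positivity."""
    out = clip_intensities(cells, cfg, panel)
    out = filter_cells_by_area(out, cfg)
    return call_positive_cells(out, cfg, panel)
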