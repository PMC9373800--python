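"""Model/Results interface tying the pipeline stages together.

:class:`LocalCoexpression` holds a validated cell table, the marker panel
and the QC/scan configurations; :meth:`LocalCoexpression.fit` runs
QC -> gating -> window scan -> co-expression scoring -> empirical
significance and returns a :class:`LocalCoexpressionResults` carrying the
per-window estimates, their empirical p-values and diagnostics, with
``summary()``, CSV/GeoJSON export and plotting attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qc as _qc
from . import stats as _stats
from . import viz as _viz
from .core import (
    MarkerPanel,
    QCConfig,
    ScanConfig,
    WindowSet,
    positive_col,
    validate_cell_table,
    windows_to_geojson,
    write_windows_csv,
)
from .windowing import scan_windows

__all__ = ["LocalCoexpression", "LocalCoexpressionResults"]


class LocalCoexpression:
    """Ligand-receptor local co-expression model for one tissue section.

    Parameters
    ----------
    cells
        Per-cell measurement table (see :func:`lrscan.core.validate_cell_table`
        for the dialect).  If it already carries ``<marker>_positive``
        columns for every panel marker (e.g. from clustering-based
        phenotyping) gating is skipped and the calls are used as-is.
    panel
        Marker panel with the target ligand-receptor pair.
    image_extent
        ``(width, height)`` in pixels; inferred from the cell bounding box
        when omitted.
    scan, qc
        Scan and QC configurations (defaults follow the package defaults:
        95th-percentile clipping, 5th-percentile area cut, <=100 cells per
        window, quadrant subdivision).
    reference_round
        Pooled multi-round tables only: the round whose cells define window
        totals and split decisions.

    Examples
    --------
    >>> model = LocalCoexpression(cells, panel, qc=qc_cfg)
    >>> res = model.fit(alpha=0.05)
    >>> res.summary()           # doctest: +SKIP
    >>> res.to_csv("windows.csv")       # doctest: +SKIP
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        panel: MarkerPanel,
        image_extent: tuple[float, float] | None = None,
        scan: ScanConfig | None = None,
        qc: QCConfig | None = None,
        reference_round: str | None = None,
    ):
        self.panel = panel
        self.cells = validate_cell_table(cells, panel)
        self.scan_config = scan or ScanConfig()
        self.qc_config = qc or QCConfig()
        self.reference_round = reference_round
        if image_extent is None:
            if not len(self.cells):
                raise ValueError("cannot infer image extent from an empty cell table")
            image_extent = (
                float(np.ceil(self.cells["x"].max() + 1)),
                float(np.ceil(self.cells["y"].max() + 1)),
            )
        self.image_extent = (float(image_extent[0]), float(image_extent[1]))

    @classmethod
    def from_csv(cls, path, panel: MarkerPanel, **kwargs) -> "LocalCoexpression":
        from .core import read_cell_table

        return cls(read_cell_table(path, panel), panel, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, alpha: float = 0.05, bh_correction: bool = False) -> "LocalCoexpressionResults":
        """Run the full pipeline and return per-window results."""
        panel = self.panel
        cells = self.cells
        n_in = len(cells)

        have_calls = all(positive_col(m) in cells.columns for m in panel.markers)
        if have_calls:
            qc_cells = cells
        else:
            qc_cells = _qc.clip_intensities(cells, self.qc_config, panel)
            qc_cells = _qc.filter_cells_by_area(qc_cells, self.qc_config)
            qc_cells = _qc.call_positive_cells(qc_cells, self.qc_config, panel)

        windows = scan_windows(
            qc_cells, self.image_extent, self.scan_config, panel, self.reference_round
        )
        scores = _stats.score_all_windows(windows, panel)
        sig = _stats.empirical_significance(scores, alpha=alpha, bh_correction=bh_correction)
        table = windows.to_frame().merge(
            sig.reset_index(), on="window_id", validate="one_to_one"
        )
        if len(table):
            table["minmax_score"] = _stats.normalize_minmax(
                table["coexpression_score"].to_numpy()
            )
        else:
            table["minmax_score"] = pd.Series([], dtype=float)
        return LocalCoexpressionResults(
            model=self,
            windows=table,
            window_set=windows,
            cells=qc_cells,
            alpha=alpha,
            n_cells_in=n_in,
            gated=not have_calls,
        )


@dataclass
class LocalCoexpressionResults:
    """Fitted per-window co-expression map.

    Attributes
    ----------
    windows
        One row per retained leaf window: bounds, depth, per-marker positive
        counts, co-expression score, background size, percentile, p-value,
        ``neg_log10_p``, min-max-normalised score and the significance call.
    cells
        The post-QC cell table actually scanned (with positivity columns).
    """

    model: LocalCoexpression
    windows: pd.DataFrame
    window_set: WindowSet
    cells: pd.DataFrame
    alpha: float
    n_cells_in: int
    gated: bool
    extra: dict = field(default_factory=dict)

    # -- scalar diagnostics -------------------------------------------------
    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_tested(self) -> int:
        return int((self.windows["coexpression_score"] > 0).sum())

    @property
    def n_significant(self) -> int:
        return int(self.windows["significant"].sum())

    def summary(self) -> str:
        """Human-readable run summary (counts, window bookkeeping, top windows)."""
        m = self.model
        lines = [
            "Ligand-receptor local co-expression",
            "=" * 51,
            f"target pair:        {m.panel.target_ligand} -> {m.panel.target_receptor}",
            f"panel:              {', '.join(m.panel.markers)} (n={m.panel.n_markers})",
            f"image extent:       {m.image_extent[0]:.0f} x {m.image_extent[1]:.0f} px",
            f"cells in / scanned: {self.n_cells_in} / {len(self.cells)}"
            + ("" if self.gated else "  (positivity supplied, gating skipped)"),
            f"windows retained:   {self.n_windows} "
            f"(discarded {self.window_set.discarded_count}, "
            f"forced {self.window_set.forced_count})",
            f"windows tested:     {self.n_tested} (score > 0)",
            f"significant:        {self.n_significant} at alpha={self.alpha:g}",
        ]
        sig = self.windows.loc[self.windows["significant"]].nlargest(5, "neg_log10_p")
        if len(sig):
            lines.append("top windows (by -log10 p):")
            for _, r in sig.iterrows():
                lines.append(
                    f"  {r['window_id']}  [{r['x0']:.0f},{r['y0']:.0f})x"
                    f"[{r['x1']:.0f},{r['y1']:.0f})  score={r['coexpression_score']:.3f}"
                    f"  p={r['p_value']:.4g}"
                )
        return "\n".join(lines)

    # -- export -------------------------------------------------------------
    def to_csv(self, path) -> None:
        write_windows_csv(self.windows, path)

    def to_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(windows_to_geojson(self.windows), fh, indent=1)

    # -- plotting -----------------------------------------------------------
    def plot_activity_map(self, out=None, **kwargs):
        """Render the significance heatmap; see :func:`lrscan.viz.render_activity_map`."""
        return _viz.render_activity_map(self.windows, out=out, **kwargs)

    def plot_marker(self, marker: str, out=None, **kwargs):
        return _viz.plot_marker_expression(self.cells, marker, out=out, **kwargs)
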