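"""End-to-end pipeline driven by a single YAML config.

Stages: ingest -> (register + merge, when a second round is given) -> QC ->
gating -> window scan -> scoring -> significance -> rendering.  Every stage
logs its parameters and in/out counts; any failure aborts with the stage
name and cause.  Outputs under the chosen directory: ``results.csv`` (one
row per leaf window), ``results.geojson``, ``map.png``, ``run_meta.json``
and ``run.log``.  Given the same config and seed, two runs produce
byte-identical result CSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from .core import GateSpec, MarkerPanel, QCConfig, ScanConfig, read_cell_table
from .model import LocalCoexpression, LocalCoexpressionResults
from .registration import apply_transform, estimate_round_transform, merge_rounds

__all__ = ["PipelineError", "load_config", "run_pipeline"]

log = logging.getLogger("lrscan")


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


@_stage("panel")
def _build_panel(cfg: dict) -> MarkerPanel:
    try:
        p = cfg["panel"]
        return MarkerPanel(
            markers=tuple(p["markers"]),
            target_ligand=p["ligand"],
            target_receptor=p["receptor"],
            known_lr_pairs=tuple(tuple(x) for x in p.get("known_lr_pairs", [])),
        )
    except KeyError as exc:
        raise KeyError(f"missing config key under 'panel': {exc}") from exc


def _build_qc(cfg: dict) -> QCConfig:
    q = dict(cfg.get("qc", {}))
    gates = {
        m: GateSpec(method=g.get("method", "otsu"), value=g.get("value"))
        for m, g in q.pop("gates", {}).items()
    }
    return QCConfig(gates=gates, **q)


def _build_scan(cfg: dict) -> ScanConfig:
    return ScanConfig(**cfg.get("scan", {}))


def run_pipeline(config_path, outdir) -> LocalCoexpressionResults:
    """Run the configured analysis end to end and write all outputs.

    Parameters
    ----------
    config_path
        YAML file with sections ``input`` (cells, optional cells_round2 and
        round2_markers, optional extent), ``panel``, and optional ``qc``,
        ``scan``, ``stats`` (alpha, bh_correction), ``registration`` (kind,
        max_iter) and ``viz`` (value_field, colormap, contour, background).
    outdir
        Output directory, created if needed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(load_config(config_path), Path(config_path).parent, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def _run(cfg: dict, base: Path, outdir: Path) -> LocalCoexpressionResults:
    panel = _build_panel(cfg)
    qc_cfg = _build_qc(cfg)
    scan_cfg = _build_scan(cfg)
    stats_cfg = cfg.get("stats", {})
    meta: dict = {"panel": {"markers": list(panel.markers),
                            "ligand": panel.target_ligand,
                            "receptor": panel.target_receptor}}

    @_stage("ingest")
    def ingest():
        inp = cfg.get("input", {})
        if "cells" not in inp:
            raise KeyError("missing config key 'input.cells'")
        if inp.get("cells_round2"):
            # each round carries only its own markers; the pooled table is
            # validated against the full panel after merging
            import pandas as pd

            cells = pd.read_csv(_resolve(base, inp["cells"]))
        else:
            cells = read_cell_table(_resolve(base, inp["cells"]), panel)
        log.info("ingest: %d cells from %s", len(cells), inp["cells"])
        return inp, cells

    inp, cells = ingest()
    reference_round = None

    if inp.get("cells_round2"):

        @_stage("registration")
        def register():
            import pandas as pd

            reg = cfg.get("registration", {})
            moving = pd.read_csv(_resolve(base, inp["cells_round2"]))
            t = estimate_round_transform(
                cells,
                moving,
                kind=reg.get("kind", "rigid"),
                max_iter=int(reg.get("max_iter", 100)),
            )
            log.info("registration: kind=%s residual=%.4f px", t.kind, t.residual)
            aligned = apply_transform(moving, t)
            pooled = merge_rounds(cells, aligned, panel)
            return pooled, t

        cells, transform = register()
        reference_round = inp.get("reference_round", "r1")
        meta["registration"] = {
            "kind": transform.kind,
            "matrix": transform.matrix,
            "offset": transform.offset,
            "residual_px": transform.residual,
        }

    @_stage("fit")
    def fit():
        extent = inp.get("extent")
        model = LocalCoexpression(
            cells,
            panel,
            image_extent=tuple(extent) if extent else None,
            scan=scan_cfg,
            qc=qc_cfg,
            reference_round=reference_round,
        )
        res = model.fit(
            alpha=float(stats_cfg.get("alpha", 0.05)),
            bh_correction=bool(stats_cfg.get("bh_correction", False)),
        )
        log.info(
            "fit: %d cells scanned, %d windows (%d discarded, %d forced), "
            "%d tested, %d significant",
            len(res.cells),
            res.n_windows,
            res.window_set.discarded_count,
            res.window_set.forced_count,
            res.n_tested,
            res.n_significant,
        )
        return res

    results = fit()

    @_stage("export")
    def export():
        results.to_csv(outdir / "results.csv")
        results.to_geojson(outdir / "results.geojson")
        meta.update(
            {
                "n_cells_in": results.n_cells_in,
                "n_cells_scanned": len(results.cells),
                "n_windows": results.n_windows,
                "n_discarded": results.window_set.discarded_count,
                "n_forced": results.window_set.forced_count,
                "n_tested": results.n_tested,
                "n_significant": results.n_significant,
                "alpha": results.alpha,
            }
        )
        with open(outdir / "run_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    export()

    @_stage("render")
    def render():
        viz = cfg.get("viz", {})
        bg = viz.get("background")
        results.plot_activity_map(
            out=outdir / "map.png",
            value_field=viz.get("value_field", "neg_log10_p"),
            cmap=viz.get("colormap", "inferno"),
            contour=bool(viz.get("contour", True)),
            background=str(_resolve(base, bg)) if bg else None,
        )

    render()
    log.info("pipeline complete: outputs in %s", outdir)
    return results
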