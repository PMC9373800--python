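from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lrscan import GateSpec, MarkerPanel, QCConfig, ScanConfig

MARKERS = ("LIG", "REC", "M3", "M4", "M5")


@pytest.fixture
def panel5() -> MarkerPanel:
    return MarkerPanel(markers=MARKERS, target_ligand="LIG", target_receptor="REC")


@pytest.fixture
def panel3() -> MarkerPanel:
    return MarkerPanel(markers=("LIG", "REC", "M3"), target_ligand="LIG", target_receptor="REC")


@pytest.fixture
def valley_qc() -> QCConfig:
    """Benchmark QC: clip above the expected positive fraction, gate at the
    inter-mode valley of the simulator's intensity mixture."""
    return QCConfig(
        clip_percentile=99.5,
        gates={m: GateSpec("manual", 17.0) for m in MARKERS},
    )


def make_cells(
    x,
    y,
    markers=MARKERS,
    positive: dict[str, np.ndarray] | None = None,
    intensities: dict[str, np.ndarray] | None = None,
    area=10.0,
) -> pd.DataFrame:
    """Minimal valid cell table from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": x,
            "y": y,
            "area": np.full(n, area, dtype=float) if np.isscalar(area) else np.asarray(area, float),
        }
    )
    for m in markers:
        df[f"{m}_mean"] = (
            intensities[m] if intensities and m in intensities else np.ones(n)
        )
        if positive is not None:
            df[f"{m}_positive"] = positive.get(m, np.zeros(n, dtype=bool))
    return df


def random_scan_instance(seed: int, markers=MARKERS):
    """Random scan problem: cells (some clustered), positivity, extent, config.

    Kept small (<= 300 cells) so the recursive oracle stays cheap.
    """
    rng = np.random.default_rng(seed)
    extent = (float(rng.integers(200, 1200)), float(rng.integers(200, 1200)))
    n_uniform = int(rng.integers(0, 220))
    n_clust = int(rng.integers(0, 80))
    cx, cy = rng.random(2) * extent
    x = np.concatenate([rng.random(n_uniform) * extent[0], np.clip(cx + rng.normal(0, 20, n_clust), 0, extent[0] - 1e-9)])
    y = np.concatenate([rng.random(n_uniform) * extent[1], np.clip(cy + rng.normal(0, 20, n_clust), 0, extent[1] - 1e-9)])
    positive = {m: rng.random(len(x)) < rng.uniform(0.05, 0.5) for m in markers}
    cfg = ScanConfig(
        cell_count_threshold=int(rng.integers(10, 80)),
        min_cells=2,
        subset_rate=float(rng.choice([0.5, 0.5, 0.5, 0.4, 0.34])),
        init_rate=float(rng.choice([0.125, 0.25, 0.3, 0.5])),
        min_window_edge=float(rng.choice([4.0, 16.0, 32.0])),
    )
    cells = make_cells(x, y, markers=markers, positive=positive)
    return cells, extent, cfg
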