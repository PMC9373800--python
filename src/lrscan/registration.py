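"""Point-set registration of imaging rounds.

Iterative stain-strip assays image different markers in different rounds; the
rounds must share a coordinate frame before cells can be pooled into common
windows.  Registration here operates on the detected cell centroids of the
nuclear (DAPI) channel: an iterative-closest-point loop alternates
nearest-neighbour correspondence (moving -> fixed) with a closed-form
least-squares fit of the requested transform family, after an initial
centre-of-mass alignment.  Because ICP is a local optimiser, families with a
rotation are additionally multi-started from a small grid of initial angles
and the start with the best final residual wins; estimation is fully
deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ConfigError, EstimationError, MarkerPanel, TransformParams, intensity_col

__all__ = ["estimate_round_transform", "apply_transform", "merge_rounds"]

_ROTATION_STARTS_DEG = (0.0, -12.0, -8.0, -4.0, 4.0, 8.0, 12.0)


def _fit_translation(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.eye(2), dst.mean(axis=0) - src.mean(axis=0)


def _fit_procrustes(
    src: np.ndarray, dst: np.ndarray, with_scale: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation (optionally scaled) + offset (Kabsch/Umeyama)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    s, d = src - mu_s, dst - mu_d
    cov = d.T @ s / len(src)
    u, sing, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, sign])
    rot = u @ diag @ vt
    if with_scale:
        var_s = (s**2).sum() / len(src)
        if var_s <= 0:
            raise EstimationError("degenerate source geometry: zero spread")
        scale = (sing * np.diag(diag)).sum() / var_s
        rot = scale * rot
    return rot, mu_d - rot @ mu_s


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(src)
    design = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise EstimationError("degenerate geometry: collinear points cannot fix an affine map")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return sol[:2].T, sol[2]


_FITTERS = {
    "translation": lambda s, d: _fit_translation(s, d),
    "rigid": lambda s, d: _fit_procrustes(s, d, with_scale=False),
    "similarity": lambda s, d: _fit_procrustes(s, d, with_scale=True),
    "affine": lambda s, d: _fit_affine(s, d),
}


def _icp(
    fixed: np.ndarray,
    moving: np.ndarray,
    kind: str,
    init_A: np.ndarray,
    init_t: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    tree = cKDTree(fixed)
    A, t = init_A, init_t
    prev = np.inf
    residual = np.inf
    for _ in range(max_iter):
        cur = moving @ A.T + t
        dist, idx = tree.query(cur)
        residual = float(dist.mean())
        if prev - residual < tol:
            break
        prev = residual
        A, t = _FITTERS[kind](moving, fixed[idx])
    return A, t, residual


def estimate_round_transform(
    fixed: pd.DataFrame,
    moving: pd.DataFrame,
    kind: str = "rigid",
    max_iter: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
) -> TransformParams:
    """Estimate the transform mapping *moving* centroids onto *fixed*.

    Parameters
    ----------
    fixed, moving
        Cell tables (only their ``x``/``y`` columns are used); both need at
        least 3 cells.
    kind
        ``translation``, ``rigid``, ``similarity`` or ``affine``.
    max_iter
        ICP iteration cap; iteration also stops once the mean residual
        improves by less than *tol* pixels.
    seed
        Unused by the estimator (it is deterministic); accepted so call
        sites that thread a seed through simulation and estimation share a
        signature.

    Returns
    -------
    TransformParams with the final mean nearest-neighbour residual.
    """
    if kind not in _FITTERS:
        raise ConfigError(f"unknown transform kind {kind!r}")
    fx = fixed[["x", "y"]].to_numpy(dtype=float)
    mv = moving[["x", "y"]].to_numpy(dtype=float)
    if len(fx) < 3 or len(mv) < 3:
        raise EstimationError("registration needs at least 3 cells in each round")

    # centre-of-mass pre-alignment
    shift = fx.mean(axis=0) - mv.mean(axis=0)
    if kind == "translation":
        starts = [(np.eye(2), shift)]
    else:
        starts = []
        centre = mv.mean(axis=0)
        for deg in _ROTATION_STARTS_DEG:
            th = np.deg2rad(deg)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            starts.append((rot, fx.mean(axis=0) - rot @ centre))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for A0, t0 in starts:
        A, t, res = _icp(fx, mv, kind, A0, t0, max_iter, tol)
        if best is None or res < best[0]:
            best = (res, A, t)
    res, A, t = best
    return TransformParams(
        kind=kind, matrix=tuple(map(tuple, A)), offset=tuple(t)
    ).with_residual(res)


def apply_transform(cells: pd.DataFrame, t: TransformParams) -> pd.DataFrame:
    """Return a copy of *cells* with centroids mapped through *t*.

    Every non-coordinate column is carried over unchanged.
    """
    out = cells.copy()
    xy = t.apply(out[["x", "y"]].to_numpy(dtype=float))
    out["x"] = xy[:, 0]
    out["y"] = xy[:, 1]
    return out


def merge_rounds(
    round1: pd.DataFrame, round2_aligned: pd.DataFrame, panel: MarkerPanel
) -> pd.DataFrame:
    """Pool an aligned second round with the reference round.

    Each marker must be imaged in exactly one round (its intensity column
    present in that round's table only); the pooled table keeps ``round_id``
    so that downstream windowing can count totals from the reference round
    while taking each marker's positive cells from the round that carries it.
    """
    cols1 = {c for c in round1.columns}
    cols2 = {c for c in round2_aligned.columns}
    for m in panel.markers:
        if intensity_col(m) in cols1 and intensity_col(m) in cols2:
            raise ConfigError(
                f"marker {m!r} is present in both rounds; each marker must be "
                "imaged in exactly one round"
            )
    r1 = round1.copy()
    r2 = round2_aligned.copy()
    rounds1 = set(r1.get("round_id", pd.Series(dtype=str)).unique())
    rounds2 = set(r2.get("round_id", pd.Series(dtype=str)).unique())
    if rounds1 & rounds2:
        raise ConfigError(f"rounds share round_id labels {sorted(rounds1 & rounds2)}")
    pooled = pd.concat([r1, r2], ignore_index=True, sort=False)
    if pooled["cell_id"].duplicated().any():
        pooled["cell_id"] = pooled["round_id"].astype(str) + ":" + pooled["cell_id"].astype(str)
    # markers not measured in a round: treat as not positive there
    for m in panel.markers:
        pc = f"{m}_positive"
        if pc in pooled.columns:
            pooled[pc] = pooled[pc].notna() & pooled[pc].eq(True)
    return pooled
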