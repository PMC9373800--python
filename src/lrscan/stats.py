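"""Window-level co-expression scoring and empirical significance.

The co-expression score of a window is the fraction of its cells positive
for the ligand plus the fraction positive for the receptor,

    score = (n_ligand + n_receptor) / n_total,

set to 0 whenever either count is 0: local co-expression requires both
partners present.  A double-positive cell contributes to both counts, so the
score ranges over [0, 2].

Significance is empirical, with a two-part null per window: (a) the same
score computed for every non-interacting marker pair of the panel inside the
*same* window (is the target pair enriched here beyond arbitrary marker
pairs?), and (b) the target pair's scores in every *other* score-positive
window (is this window enriched beyond the rest of the tissue?).  A window's
score is ranked against the merged background with ties counted in favour of
the observed score; the reported p-value is the add-one complement

    p = (|B| - n_beaten + 1) / (|B| + 1),

a strictly decreasing transform of the background percentile, so -log10(p)
is large exactly where the window beats most of its background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ConfigError, MarkerPanel, WindowSet, positive_col

__all__ = [
    "coexpression_score",
    "enumerate_background_pairs",
    "score_all_windows",
    "empirical_significance",
    "normalize_minmax",
    "bh_adjust",
    "shuffle_null_significance",
]

TARGET_COL = "target_lr"


def coexpression_score(n_ligand: int, n_receptor: int, n_total: int) -> float:
    """Local co-expression score of one window (range [0, 2])."""
    if n_total <= 0:
        raise ValueError("n_total must be positive; empty windows are not scored")
    if not (0 <= n_ligand <= n_total and 0 <= n_receptor <= n_total):
        raise ValueError("marker-positive counts must lie in [0, n_total]")
    if n_ligand == 0 or n_receptor == 0:
        return 0.0
    return (n_ligand + n_receptor) / n_total


def enumerate_background_pairs(panel: MarkerPanel) -> list[tuple[str, str]]:
    """Unordered non-interacting marker pairs forming the random-pair null.

    All C(n, 2) = n(n-1)/2 unordered pairs of the n panel markers, minus the
    target ligand-receptor pair and any declared ``known_lr_pairs``, in panel
    order.  With fewer than 3 markers no non-target pair exists.
    """
    if panel.n_markers < 3:
        raise ConfigError(
            "background-pair null needs at least 3 markers; add non-interacting "
            "markers to the panel or use the within-window label-shuffle null"
        )
    excluded = {panel.target_pair}
    excluded.update(frozenset(p) for p in panel.known_lr_pairs)
    pairs = []
    for i, a in enumerate(panel.markers):
        for b in panel.markers[i + 1 :]:
            if frozenset((a, b)) not in excluded:
                pairs.append((a, b))
    return pairs


def _pair_col(a: str, b: str) -> str:
    return f"{a}|{b}"


def score_all_windows(windows: WindowSet, panel: MarkerPanel) -> pd.DataFrame:
    """Score every leaf window for the target pair and every background pair.

    Returns a frame indexed by ``window_id`` with one column per pair; the
    target pair's column is named ``target_lr``.  The score is symmetric in
    the pair, so background pairs need no ligand/receptor orientation.
    """
    bg_pairs = enumerate_background_pairs(panel)
    records = {}
    for w in windows.leaves:
        row = {
            TARGET_COL: coexpression_score(
                w.marker_counts[panel.target_ligand],
                w.marker_counts[panel.target_receptor],
                w.n_total_cells,
            )
        }
        for a, b in bg_pairs:
            row[_pair_col(a, b)] = coexpression_score(
                w.marker_counts[a], w.marker_counts[b], w.n_total_cells
            )
        records[w.window_id] = row
    cols = [TARGET_COL] + [_pair_col(a, b) for a, b in bg_pairs]
    return pd.DataFrame.from_dict(records, orient="index", columns=cols).rename_axis(
        "window_id"
    )


def empirical_significance(
    scores: pd.DataFrame, alpha: float = 0.05, bh_correction: bool = False
) -> pd.DataFrame:
    """Rank each window's target score against its merged background.

    Parameters
    ----------
    scores
        Output of :func:`score_all_windows` (``target_lr`` column plus one
        column per background pair).
    alpha
        Significance level applied to ``p_value`` (after BH adjustment when
        ``bh_correction`` is on).
    bh_correction
        Optional Benjamini-Hochberg adjustment across tested windows.  Off by
        default; the base method applies no multiple-testing correction.

    Returns
    -------
    DataFrame indexed like *scores* with columns ``coexpression_score``,
    ``background_size``, ``n_beaten``, ``percentile``, ``p_value``,
    ``neg_log10_p``, ``significant`` and ``untestable``.  Windows with score
    0 are not tested (p = 1); a positive window with an empty background is
    flagged untestable.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    s = scores[TARGET_COL].to_numpy(dtype=float)
    bg = scores.drop(columns=[TARGET_COL]).to_numpy(dtype=float)
    n_win = len(s)
    pos = s > 0

    # Same-pair half of the background: target scores of the other positive
    # windows.  Sorted once; each positive window removes itself.
    pos_scores = np.sort(s[pos])
    n_pos = pos_scores.size

    background_size = np.zeros(n_win, dtype=int)
    n_beaten = np.zeros(n_win, dtype=int)
    for i in range(n_win):
        if not pos[i]:
            continue
        m_same = n_pos - 1
        background_size[i] = bg.shape[1] + m_same
        # ties count as beaten (>= comparator); subtract self from the pool
        beaten_same = int(np.searchsorted(pos_scores, s[i], side="right")) - 1
        n_beaten[i] = int((s[i] >= bg[i]).sum()) + beaten_same

    percentile = np.zeros(n_win, dtype=float)
    tested = pos & (background_size > 0)
    percentile[tested] = n_beaten[tested] / background_size[tested]
    p_value = np.ones(n_win, dtype=float)
    p_value[tested] = (background_size[tested] - n_beaten[tested] + 1) / (
        background_size[tested] + 1
    )
    untestable = pos & (background_size == 0)

    out = pd.DataFrame(
        {
            "coexpression_score": s,
            "background_size": background_size,
            "n_beaten": n_beaten,
            "percentile": percentile,
            "p_value": p_value,
        },
        index=scores.index,
    )
    if bh_correction:
        out["p_adjusted"] = 1.0
        out.loc[tested, "p_adjusted"] = bh_adjust(p_value[tested])
        p_for_call = out["p_adjusted"].to_numpy()
    else:
        p_for_call = p_value
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out["significant"] = tested & (p_for_call <= alpha)
    out["untestable"] = untestable
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def normalize_minmax(values) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("normalize_minmax needs at least one value")
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def shuffle_null_significance(
    cells: pd.DataFrame,
    windows: WindowSet,
    panel: MarkerPanel,
    n_permutations: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fallback null for panels with fewer than 3 markers.

    The ligand and receptor positivity labels are independently shuffled
    across *all* cells of the tissue ``n_permutations`` times and the
    window's score recomputed under each shuffle; tissue-wide positive
    fractions are preserved while spatial clustering of positives is broken.
    (A shuffle restricted to one window would leave the count-ratio score
    unchanged and carry no information.)  Each shuffle draws the window's
    positive counts from the corresponding hypergeometric law, which is
    distributionally identical to materialising the permuted labels.  The
    permutation scores are merged with the target scores of the other
    positive windows exactly as in :func:`empirical_significance`.  This
    null is a documented deviation from the background-pair construction and
    is only used when requested.
    """
    rng = np.random.default_rng(seed)
    lig = cells[positive_col(panel.target_ligand)].to_numpy(dtype=bool)
    rec = cells[positive_col(panel.target_receptor)].to_numpy(dtype=bool)
    n_cells, n_lig, n_rec = len(cells), int(lig.sum()), int(rec.sum())

    obs = np.array(
        [
            coexpression_score(
                w.marker_counts[panel.target_ligand],
                w.marker_counts[panel.target_receptor],
                w.n_total_cells,
            )
            for w in windows.leaves
        ]
    )
    pos = obs > 0
    pos_sorted = np.sort(obs[pos])

    rows = []
    for i, w in enumerate(windows.leaves):
        if not pos[i]:
            rows.append((obs[i], 0, 0, 0.0, 1.0))
            continue
        nt = w.n_total_cells
        pl = rng.hypergeometric(n_lig, n_cells - n_lig, nt, size=n_permutations)
        pr = rng.hypergeometric(n_rec, n_cells - n_rec, nt, size=n_permutations)
        perm = np.where((pl > 0) & (pr > 0), (pl + pr) / nt, 0.0)
        same = np.searchsorted(pos_sorted, obs[i], side="right") - 1
        bsize = n_permutations + (pos_sorted.size - 1)
        beaten = int((obs[i] >= perm).sum()) + int(same)
        pct = beaten / bsize
        pval = (bsize - beaten + 1) / (bsize + 1)
        rows.append((obs[i], bsize, beaten, pct, pval))
    out = pd.DataFrame(
        rows,
        columns=["coexpression_score", "background_size", "n_beaten", "percentile", "p_value"],
        index=[w.window_id for w in windows.leaves],
    ).rename_axis("window_id")
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out["significant"] = (out["coexpression_score"] > 0) & (out["p_value"] <= alpha)
    out["untestable"] = False
    return out
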