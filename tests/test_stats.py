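import numpy as np
import pandas as pd
import pytest

from lrscan import (
    ConfigError,
    MarkerPanel,
    ScanConfig,
    coexpression_score,
    empirical_significance,
    enumerate_background_pairs,
    normalize_minmax,
    scan_windows,
    score_all_windows,
)
from lrscan.stats import TARGET_COL, bh_adjust, shuffle_null_significance

from conftest import make_cells, random_scan_instance
from oracles import pair_score, significance_bruteforce


class TestCoexpressionScore:
    @pytest.mark.parametrize(
        "nl,nr,nt,expected",
        [
            (3, 2, 10, 0.5),
            (0, 5, 10, 0.0),
            (5, 0, 10, 0.0),
            (5, 5, 5, 2.0),  # all cells double-positive
            (1, 1, 2, 1.0),
        ],
    )
    def test_examples(self, nl, nr, nt, expected):
        assert coexpression_score(nl, nr, nt) == expected

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            coexpression_score(0, 0, 0)

    def test_range_and_zero_iff_one_side_empty(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            nt = int(rng.integers(1, 50))
            nl = int(rng.integers(0, nt + 1))
            nr = int(rng.integers(0, nt + 1))
            s = coexpression_score(nl, nr, nt)
            assert 0.0 <= s <= 2.0
            assert (s == 0.0) == (nl == 0 or nr == 0)

    def test_adding_ligand_cell_never_decreases(self):
        """Adding one ligand-positive cell to a receptor-containing window
        never lowers the score, as long as positives don't already outnumber
        cells (no double-positive saturation)."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            nt = int(rng.integers(1, 40))
            nl = int(rng.integers(0, nt + 1))
            nr = int(rng.integers(1, nt + 1))
            if nl + nr > nt:
                continue
            assert coexpression_score(nl + 1, nr, nt + 1) >= coexpression_score(nl, nr, nt)
        # from zero ligand cells, any addition turns the score positive
        assert coexpression_score(1, 3, 11) > coexpression_score(0, 3, 10)


class TestBackgroundPairs:
    def test_five_marker_panel_counts(self, panel5):
        pairs = enumerate_background_pairs(panel5)
        n = panel5.n_markers
        assert n * (n - 1) // 2 == 10
        assert len(pairs) == 9
        assert all(frozenset(p) != frozenset(("LIG", "REC")) for p in pairs)

    def test_three_marker_panel(self, panel3):
        assert len(enumerate_background_pairs(panel3)) == 2

    def test_two_marker_panel_rejected(self):
        panel = MarkerPanel(markers=("A", "B"), target_ligand="A", target_receptor="B")
        with pytest.raises(ConfigError, match="3 markers"):
            enumerate_background_pairs(panel)

    def test_known_lr_pairs_excluded(self):
        panel = MarkerPanel(
            markers=("L1", "R1", "L2", "R2", "X"),
            target_ligand="L1",
            target_receptor="R1",
            known_lr_pairs=(("L2", "R2"),),
        )
        pairs = enumerate_background_pairs(panel)
        assert len(pairs) == 8
        assert all(frozenset(p) != frozenset(("L2", "R2")) for p in pairs)

    def test_deterministic_order(self, panel5):
        assert enumerate_background_pairs(panel5) == enumerate_background_pairs(panel5)


class TestScoreAllWindows:
    def test_single_window_counts(self, panel5):
        positive = {
            "LIG": np.array([1, 1, 0, 0], bool),
            "REC": np.array([0, 0, 1, 1], bool),
            "M3": np.zeros(4, bool),
            "M4": np.zeros(4, bool),
            "M5": np.array([1, 1, 1, 0], bool),
        }
        cells = make_cells([10, 20, 30, 40], [10, 20, 30, 40], positive=positive)
        ws = scan_windows(cells, (100, 100), ScanConfig(init_rate=1.0), panel5)
        scores = score_all_windows(ws, panel5)
        assert scores.shape == (1, 10)
        assert scores[TARGET_COL].iloc[0] == 1.0  # (2+2)/4
        assert scores["M3|M4"].iloc[0] == 0.0
        assert scores["LIG|M5"].iloc[0] == pytest.approx((2 + 3) / 4)

    def test_matches_bruteforce_recomputation(self, panel5):
        cells, extent, cfg = random_scan_instance(11)
        ws = scan_windows(cells, extent, cfg, panel5)
        scores = score_all_windows(ws, panel5)
        for w in ws.leaves:
            for (a, b) in enumerate_background_pairs(panel5):
                expected = pair_score(w.marker_counts[a], w.marker_counts[b], w.n_total_cells)
                assert scores.at[w.window_id, f"{a}|{b}"] == expected
            assert scores.at[w.window_id, TARGET_COL] == pair_score(
                w.marker_counts["LIG"], w.marker_counts["REC"], w.n_total_cells
            )


class TestEmpiricalSignificance:
    def _frame(self, target, background_rows):
        n_bg = len(background_rows[0])
        return pd.DataFrame(
            np.column_stack([target, background_rows]),
            columns=[TARGET_COL] + [f"b{i}" for i in range(n_bg)],
            index=[f"w{i}" for i in range(len(target))],
        )

    def test_beating_all_99_gives_p_001(self):
        """One window above an all-zero background of 9 pairs, plus 90 other
        positive windows it also beats: percentile 1, p = 1/100."""
        rng = np.random.default_rng(2)
        target = np.concatenate([[2.0], rng.uniform(0.01, 1.0, 90)])
        bg = np.zeros((91, 9))
        res = empirical_significance(self._frame(target, bg))
        assert res.loc["w0", "background_size"] == 99
        assert res.loc["w0", "percentile"] == 1.0
        assert res.loc["w0", "p_value"] == pytest.approx(0.01)
        assert res.loc["w0", "neg_log10_p"] == pytest.approx(2.0)

    def test_all_ties_count_as_beaten(self):
        target = np.full(5, 0.5)
        bg = np.full((5, 3), 0.5)
        res = empirical_significance(self._frame(target, bg))
        # background: 3 pair scores + 4 other positive windows, all tied
        assert (res["background_size"] == 7).all()
        assert (res["percentile"] == 1.0).all()
        np.testing.assert_allclose(res["p_value"].to_numpy(), 1 / 8)

    def test_zero_score_windows_not_tested(self):
        target = np.array([0.0, 0.4, 0.6])
        bg = np.full((3, 4), 0.1)
        res = empirical_significance(self._frame(target, bg))
        assert res.loc["w0", "p_value"] == 1.0
        assert not res.loc["w0", "significant"]
        # zero-score window excluded from others' same-pair background
        assert res.loc["w1", "background_size"] == 4 + 1

    def test_monotone_in_score(self):
        bg = np.tile(np.linspace(0, 1, 8), (6, 1))
        target = np.array([0.05, 0.2, 0.4, 0.6, 0.8, 1.5])
        res = empirical_significance(self._frame(target, bg))
        p = res["p_value"].to_numpy()
        assert (np.diff(p) <= 1e-12).all()

    def test_oracle_equivalence_on_scan_instances(self, panel5):
        for seed in (3, 4, 5):
            cells, extent, cfg = random_scan_instance(seed)
            ws = scan_windows(cells, extent, cfg, panel5)
            if not ws.leaves:
                continue
            scores = score_all_windows(ws, panel5)
            mine = empirical_significance(scores)
            oracle = significance_bruteforce(scores)
            for col in ("background_size", "n_beaten"):
                np.testing.assert_array_equal(mine[col].to_numpy(), oracle[col].to_numpy())
            for col in ("percentile", "p_value"):
                np.testing.assert_allclose(mine[col].to_numpy(), oracle[col].to_numpy(), rtol=0, atol=0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigError):
            empirical_significance(self._frame(np.array([0.5]), np.zeros((1, 2))), alpha=1.5)

    def test_bh_adjustment_is_monotone_and_conservative(self):
        rng = np.random.default_rng(9)
        target = rng.uniform(0.01, 1.5, 40)
        bg = rng.uniform(0, 1.5, (40, 9))
        plain = empirical_significance(self._frame(target, bg))
        bh = empirical_significance(self._frame(target, bg), bh_correction=True)
        assert (bh["p_adjusted"].to_numpy() >= plain["p_value"].to_numpy() - 1e-12).all()
        assert bh["significant"].sum() <= plain["significant"].sum()


class TestBHAdjust:
    def test_known_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        expected = np.array([0.04, 0.04, 0.04, 0.5])
        np.testing.assert_allclose(bh_adjust(p), expected)


class TestMinMax:
    @pytest.mark.parametrize(
        "values,expected",
        [([0, 5, 10], [0, 0.5, 1]), ([7, 7, 7], [0, 0, 0]), ([3], [0])],
    )
    def test_examples(self, values, expected):
        np.testing.assert_allclose(normalize_minmax(values), expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_minmax([])


class TestShuffleNullFallback:
    def test_two_marker_panel_produces_pvalues(self):
        panel = MarkerPanel(markers=("A", "B"), target_ligand="A", target_receptor="B")
        rng = np.random.default_rng(12)
        n = 400
        positive = {"A": rng.random(n) < 0.2, "B": rng.random(n) < 0.2}
        cells = make_cells(rng.random(n) * 500, rng.random(n) * 500,
                           markers=("A", "B"), positive=positive)
        ws = scan_windows(cells, (500, 500), ScanConfig(init_rate=0.25, cell_count_threshold=60), panel)
        res = shuffle_null_significance(cells, ws, panel, n_permutations=100, seed=1)
        assert len(res) == len(ws.leaves)
        tested = res["coexpression_score"] > 0
        assert ((res.loc[tested, "p_value"] > 0) & (res.loc[tested, "p_value"] <= 1)).all()
        assert (res.loc[~tested, "p_value"] == 1.0).all()

    def test_seed_reproducible(self):
        panel = MarkerPanel(markers=("A", "B"), target_ligand="A", target_receptor="B")
        rng = np.random.default_rng(13)
        n = 200
        positive = {"A": rng.random(n) < 0.3, "B": rng.random(n) < 0.3}
        cells = make_cells(rng.random(n) * 300, rng.random(n) * 300,
                           markers=("A", "B"), positive=positive)
        ws = scan_windows(cells, (300, 300), ScanConfig(init_rate=0.5, cell_count_threshold=60), panel)
        a = shuffle_null_significance(cells, ws, panel, n_permutations=50, seed=5)
        b = shuffle_null_significance(cells, ws, panel, n_permutations=50, seed=5)
        pd.testing.assert_frame_equal(a, b)
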