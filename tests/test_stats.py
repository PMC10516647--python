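"""Stratified statistics against closed forms and enumeration oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from pelement_er.stats import (
    bh_adjust,
    cmh_general,
    cmh_permutation_pvalue,
    fisher_exact_2x2,
    kruskal_wallis,
)


class TestCmh:
    def test_perfect_homogeneity_is_zero(self):
        res = cmh_general([[[10, 10], [10, 10]], [[10, 10], [10, 10]]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_single_2x2_matches_closed_form(self):
        # (ad-bc)^2 (N-1) / (r1 r2 c1 c2) = 300^2 * 59 / 30^4
        res = cmh_general([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(300**2 * 59 / 30**4, abs=1e-9)
        assert res.df == 1

    def test_df_for_2x5x3_design(self, rng):
        tables = rng.integers(5, 30, size=(3, 2, 5))
        assert cmh_general(tables).df == 4

    def test_matches_statsmodels_on_2x2xk(self, rng):
        tables = rng.integers(5, 40, size=(4, 2, 2))
        ours = cmh_general(tables).statistic
        theirs = StratifiedTable(
            np.transpose(tables, (1, 2, 0)).astype(np.float64)
        ).test_null_odds(correction=False)
        assert ours == pytest.approx(float(theirs.statistic), abs=1e-9)

    def test_invariant_to_stratum_order(self, rng):
        tables = rng.integers(1, 25, size=(3, 2, 4))
        a = cmh_general(tables).statistic
        b = cmh_general(tables[::-1]).statistic
        assert a == pytest.approx(b, abs=1e-9)

    def test_invariant_to_consistent_row_and_column_swaps(self, rng):
        tables = rng.integers(1, 25, size=(3, 3, 4))
        a = cmh_general(tables).statistic
        swapped = tables[:, ::-1, :][:, :, ::-1]
        assert a == pytest.approx(cmh_general(swapped).statistic, abs=1e-9)

    def test_degenerate_margin_named(self):
        with pytest.raises(ValueError, match="row"):
            cmh_general([[[0, 0], [5, 7]], [[0, 0], [2, 3]]])

    def test_permutation_null_agrees_with_chi_square(self):
        """10^4 within-stratum shuffles reproduce the chi-square p-value
        within resampling error on a moderately associated table."""
        tables = [[[30, 20], [22, 28]], [[28, 22], [20, 30]]]
        p_asym = cmh_general(tables).p_value
        p_perm = cmh_permutation_pvalue(tables, n_shuffles=10_000, seed=1)
        se = np.sqrt(p_asym * (1 - p_asym) / 10_000)
        assert abs(p_perm - p_asym) < 4 * se + 0.01


def _fisher_two_sided_enumeration(table: np.ndarray) -> float:
    """Oracle: enumerate every 2x2 table with the observed margins and
    sum hypergeometric probabilities not exceeding the observed one."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d
    dist = sps.hypergeom(n, r1, c1)
    p_obs = dist.pmf(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = dist.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_fully_crossed_table(self):
        # 2 extreme tables out of C(6,3) equally likely arrangements
        assert fisher_exact_2x2([[3, 0], [0, 3]]).p_value == pytest.approx(0.1)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_matches_enumeration_for_small_tables(self, rng):
        """All-margin enumeration oracle on random tables with N <= 30."""
        for _ in range(200):
            tab = rng.integers(0, 8, size=(2, 2))
            if tab.sum() == 0 or tab.sum() > 30:
                continue
            ours = fisher_exact_2x2(tab).p_value
            assert ours == pytest.approx(_fisher_two_sided_enumeration(tab), abs=1e-10)


def _bh_step_up(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_sorted_input_gives_monotone_output(self):
        out = bh_adjust([0.001, 0.01, 0.2, 0.9])
        assert np.all(np.diff(out) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_hand_step_up_rule(self, ps):
        assert bh_adjust(ps) == pytest.approx(_bh_step_up(np.array(ps)), abs=1e-12)


class TestKruskalWallis:
    def test_worked_rank_computation(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_permuted_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2, 3], [3, 1, 2]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_observations(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_equal_squared_ranksum_z(self, rng):
        """On tie-free data, two-group H equals the squared standardized
        Wilcoxon rank-sum statistic."""
        x = rng.permutation(40)[:18].astype(float)
        y = np.setdiff1d(np.arange(40), x)[:15].astype(float)
        h = kruskal_wallis([x, y]).statistic
        z = sps.ranksums(x, y).statistic
        assert h == pytest.approx(z**2, rel=1e-9)


class TestStatsIO:
    def test_long_format_roundtrip(self, tmp_path):
        import pandas as pd

        from pelement_er.stats import cmh_general, read_stratified_tsv, test_results_frame

        df = pd.DataFrame(
            {
                "stratum": ["r1"] * 4 + ["r2"] * 4,
                "row": ["lost", "lost", "persistent", "persistent"] * 2,
                "column": ["CDS", "intron"] * 4,
                "count": [20, 10, 10, 20, 18, 12, 11, 19],
            }
        )
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        arr, strata, rows, cols = read_stratified_tsv(path)
        assert arr.shape == (2, 2, 2)
        assert arr[0].tolist() == [[20.0, 10.0], [10.0, 20.0]]
        res = cmh_general(arr)
        frame = test_results_frame([res])
        assert frame.loc[0, "method"] == "cmh-general"
        assert frame.loc[0, "p_value"] == res.p_value


class TestCmhCalibration:
    def test_type1_error_near_nominal_under_null(self, rng):
        """Null stratified tables (rows drawn from one shared column
        distribution) are rejected at close to the nominal rate."""
        n_sims, alpha, rejections = 2000, 0.05, 0
        probs = np.array([0.3, 0.3, 0.4])
        for _ in range(n_sims):
            tables = rng.multinomial(50, probs, size=(3, 2))  # K=3 strata, I=2 rows
            if cmh_general(tables).p_value < alpha:
                rejections += 1
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert rate == pytest.approx(alpha, abs=3 * se)
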