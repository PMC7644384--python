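import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

import penlaws as pl
from penlaws.errors import DegenerateError

from oracles import brute_friedman, brute_mannwhitney, brute_wilcoxon


class TestWilcoxonMatched:
    def test_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateError):
            pl.wilcoxon_matched([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_complete_dominance_one_sided(self):
        x = np.arange(10) + 1.0
        res = pl.wilcoxon_matched(x + 1.0, x, alternative="greater")
        assert res.method == "exact"
        assert res.p == pytest.approx(1.0 / 2 ** 10)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = x + rng.normal(scale=0.8, size=8)
        if seed % 2:  # exercise midrank ties
            x = np.round(x, 1)
            y = np.round(y, 1)
            if np.all(x == y):
                return
        res = pl.wilcoxon_matched(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_wilcoxon(x, y), abs=1e-12)

    def test_approx_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30) + 0.3
        res = pl.wilcoxon_matched(x, y)
        ref = sps.wilcoxon(x, y, correction=True, method="approx").pvalue
        assert res.method == "approx"
        assert res.p == pytest.approx(ref, rel=0.02)

    @given(st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        p1 = pl.wilcoxon_matched(x, y).p
        # strictly monotone map of the differences preserves ranks
        d = x - y
        d2 = np.sign(d) * (np.abs(d) ** 1.5)
        p2 = pl.wilcoxon_matched(d2, np.zeros_like(d2)).p
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = pl.mann_whitney([10, 11, 12, 13, 14], [1, 2, 3, 4, 5])
        assert res.method == "exact"
        from math import comb
        assert res.p == pytest.approx(2.0 / comb(10, 5))

    def test_identical_groups_p_one(self):
        res = pl.mann_whitney([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        g1 = rng.normal(size=6)
        g2 = rng.normal(loc=0.5, size=6)
        if seed % 2:
            g1, g2 = np.round(g1), np.round(g2)
        res = pl.mann_whitney(g1, g2)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_mannwhitney(g1, g2), abs=1e-12)

    def test_approx_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(size=15)
        g2 = rng.normal(loc=0.7, size=19)
        res = pl.mann_whitney(g1, g2)
        ref = sps.mannwhitneyu(g1, g2, method="asymptotic").pvalue
        assert res.method == "approx"
        assert res.p == pytest.approx(ref, rel=0.02)


class TestFriedman:
    def test_all_conditions_identical_gives_p_one(self):
        blocks = np.tile([[3.0, 3.0, 3.0]], (6, 1))
        res = pl.friedman(blocks)
        assert res.statistic == 0.0 and res.p == 1.0
        assert res.extra["degenerate"]

    def test_dominant_condition_exact_p(self):
        rng = np.random.default_rng(0)
        blocks = rng.normal(size=(5, 3))
        blocks[:, 2] = blocks.min(axis=1) - 1.0  # condition C always last
        res = pl.friedman(blocks)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_friedman(blocks), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        blocks = rng.normal(size=(5, 3))
        if seed % 2:
            blocks = np.round(blocks)  # within-row ties -> midranks
        res = pl.friedman(blocks)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_friedman(blocks), abs=1e-12)

    def test_untied_statistic_matches_scipy(self):
        rng = np.random.default_rng(7)
        blocks = rng.normal(size=(15, 5))
        res = pl.friedman(blocks)
        stat, p = sps.friedmanchisquare(*blocks.T)
        assert res.method == "approx"
        assert res.statistic == pytest.approx(stat, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_missing_cells_drop_subjects(self):
        rng = np.random.default_rng(8)
        blocks = rng.normal(size=(10, 3))
        blocks[2, 1] = np.nan
        res = pl.friedman(blocks)
        assert res.n == 9 and res.extra["dropped_subjects"] == 1


class TestPosthocAndBonferroni:
    def test_number_of_pairs(self):
        rng = np.random.default_rng(1)
        blocks = rng.normal(size=(10, 5)) + np.arange(5) * 2.0
        pairs = pl.posthoc_pairs(blocks)
        assert len(pairs) == 10  # C(5, 2)

    def test_adjustment_and_cap(self):
        np.testing.assert_allclose(pl.bonferroni([0.004, 0.2], m=10), [0.04, 1.0])

    def test_significance_flag_respects_alpha(self):
        rng = np.random.default_rng(2)
        blocks = rng.normal(size=(12, 3))
        blocks[:, 0] += 10.0
        pairs = pl.posthoc_pairs(blocks, alpha=0.05)
        flags = {p["pair"]: p["significant"] for p in pairs}
        assert flags[("c0", "c1")] and flags[("c0", "c2")]
        assert all(p["adjusted_p"] >= p["raw_p"] for p in pairs)
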