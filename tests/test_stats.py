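"""Rank-test toolkit: brute-force oracles, adjustment properties,
type-I calibration, interaction permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from liftbiome import stats as lb


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)


def friedman_statistic(mat: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square, written independently."""
    ranks = sps.rankdata(mat, axis=1)
    n, k = mat.shape
    rank_sums = ranks.sum(axis=0)
    a1 = (ranks**2).sum()
    c1 = n * k * (k + 1) ** 2 / 4.0
    denom = a1 - c1
    if denom <= 0:
        return 0.0
    return (k - 1) * ((rank_sums - n * (k + 1) / 2.0) ** 2).sum() / denom


def friedman_exact_p(mat: np.ndarray) -> float:
    """Exact permutation p: enumerate all (k!)^n within-block orderings."""
    n, k = mat.shape
    observed = friedman_statistic(mat)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.array([mat[i, list(combo[i])] for i in range(n)])
        total += 1
        hits += friedman_statistic(permuted) >= observed - 1e-12
    return hits / total


class TestFriedmanConover:
    def test_fully_tied_blocks(self):
        mat = np.ones((5, 3))
        res = lb.friedman_conover(mat)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(0)
        mat = rng.standard_normal((12, 4))
        res = lb.friedman_conover(mat)
        ref = sps.friedmanchisquare(*mat.T)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_toy_matrix_agrees_with_enumeration_oracle(self):
        mat = np.array(
            [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [1.0, 3.0, 2.0],
             [1.0, 2.0, 3.0]]
        )
        res = lb.friedman_conover(mat)
        assert abs(res.p - friedman_exact_p(mat)) <= 0.02

    def test_monotone_blocks_reach_minimal_design_p(self):
        mat = np.tile([1.0, 2.0, 3.0], (4, 1))
        exact = friedman_exact_p(mat)
        # every block perfectly ordered: no permutation beats it except ties
        all_stats = []
        perms = list(itertools.permutations(range(3)))
        for combo in itertools.product(perms, repeat=4):
            permuted = np.array([mat[i, list(combo[i])] for i in range(4)])
            all_stats.append(friedman_statistic(permuted))
        assert friedman_statistic(mat) == max(all_stats)
        res = lb.friedman_conover(mat)
        assert abs(res.p - exact) <= 0.02

    def test_incomplete_blocks_rejected(self):
        mat = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            lb.friedman_conover(mat)

    def test_conover_posthoc_separates_shifted_condition(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((20, 3))
        base[:, 2] += 3.0
        res = lb.friedman_conover(base, condition_names=["a", "b", "c"])
        assert res.pairwise is not None
        pw = res.pairwise.set_index(["condition_a", "condition_b"])
        assert pw.loc[("a", "c"), "adjusted_p"] < 0.05
        assert pw.loc[("b", "c"), "adjusted_p"] < 0.05
        assert pw.loc[("a", "b"), "adjusted_p"] > 0.05
        # compact letters: c isolated, a and b share a letter
        assert set(res.letters["a"]) & set(res.letters["b"])
        assert not set(res.letters["a"]) & set(res.letters["c"])


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = lb.kruskal_dunn([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.99

    def test_matches_mc_permutation_oracle(self):
        values = np.array(
            [3.1, 2.2, 4.5, 1.1, 2.8, 5.0, 4.1, 6.2, 5.7, 3.9, 2.0, 1.5,
             2.9, 3.3, 1.9]
        )
        groups = np.repeat([0, 1, 2], 5)
        res = lb.kruskal_dunn(values, groups)
        rng = np.random.default_rng(2)
        observed = sps.kruskal(*[values[groups == g] for g in range(3)])[0]
        hits = 0
        n_perm = 20000
        for _ in range(n_perm):
            g = rng.permutation(groups)
            hits += (
                sps.kruskal(*[values[g == i] for i in range(3)])[0]
                >= observed - 1e-12
            )
        assert abs(res.p - hits / n_perm) <= 0.02

    @staticmethod
    def _dunn_z(v, g, a, b):
        ranks = sps.rankdata(v)
        n = len(v)
        var = n * (n + 1) / 12.0
        na, nb = (g == a).sum(), (g == b).sum()
        return (ranks[g == a].mean() - ranks[g == b].mean()) / np.sqrt(
            var * (1 / na + 1 / nb)
        )

    def _dunn_mc_p(self, values, groups, a, b, n_perm, rng):
        observed = abs(self._dunn_z(values, groups, a, b))
        hits = 0
        for _ in range(n_perm):
            g = rng.permutation(groups)
            hits += abs(self._dunn_z(values, g, a, b)) >= observed - 1e-12
        return hits / n_perm

    def test_dunn_pairwise_matches_mc_oracle(self):
        values = np.array(
            [1.0, 2, 3, 4, 5, 3.5, 4.5, 5.5, 6.5, 7.5, 6, 7, 8, 9, 10]
        )
        groups = np.repeat([0, 1, 2], 5)
        pw = lb.kruskal_dunn(values, groups).pairwise.set_index(
            ["group_a", "group_b"]
        )
        rng = np.random.default_rng(3)
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            mc = self._dunn_mc_p(values, groups, a, b, 10000, rng)
            assert abs(pw.loc[(a, b), "p"] - mc) <= 0.02

    def test_dunn_normal_approximation_bound_at_mid_p(self):
        # at n = 5 per group the z approximation is coarser in the middle
        # of the null distribution; document the ~0.05 bound there
        values = np.array(
            [3.1, 2.2, 4.5, 1.1, 2.8, 5.0, 4.1, 6.2, 5.7, 3.9, 2.0, 1.5,
             2.9, 3.3, 1.9]
        )
        groups = np.repeat([0, 1, 2], 5)
        pw = lb.kruskal_dunn(values, groups).pairwise.set_index(
            ["group_a", "group_b"]
        )
        rng = np.random.default_rng(4)
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            mc = self._dunn_mc_p(values, groups, a, b, 10000, rng)
            assert abs(pw.loc[(a, b), "p"] - mc) <= 0.05

    def test_pairwise_p_ordering_follows_shift_order(self):
        rng = np.random.default_rng(4)
        g0 = rng.standard_normal(12)
        values = np.concatenate([g0, g0 + 1.5, g0 + 3.0])
        groups = np.repeat(["a", "b", "c"], 12)
        pw = lb.kruskal_dunn(values, groups).pairwise.set_index(
            ["group_a", "group_b"]
        )
        assert pw.loc[("a", "c"), "p"] < pw.loc[("a", "b"), "p"]
        assert pw.loc[("a", "c"), "p"] < pw.loc[("b", "c"), "p"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            lb.kruskal_dunn([1, 2, 3], [0, 0, 0])


class TestWilcoxonCC:
    def test_identical_multisets_p_near_one(self):
        res = lb.wilcoxon_cc([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.p > 0.95

    def test_matches_exact_enumeration(self):
        x = [1.2, 3.4, 2.2, 5.1, 0.7]
        y = [2.0, 4.4, 6.1, 5.5, 3.3]
        res = lb.wilcoxon_cc(x, y)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        assert abs(res.p - exact.pvalue) <= 0.02

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(12)
        ps = [
            lb.wilcoxon_cc(x, x + shift).p for shift in (0.5, 1.5, 3.0)
        ]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lb.wilcoxon_cc([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert lb.pearson_r(a, 2 * a + 1).statistic == pytest.approx(1.0)
        assert lb.pearson_r(a, -a).statistic == pytest.approx(-1.0)

    def test_toy_triple(self):
        res = lb.pearson_r([1, 2, 3], [1, 3, 2])
        assert res.statistic == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            lb.pearson_r([1, 1, 1], [1, 2, 3])


class TestAdjustments:
    def test_bh_step_up_hand_example(self):
        out = lb.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert lb.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert lb.holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        out = lb.bh_adjust([0.04, 0.04, 0.04, 0.04])
        assert np.allclose(out, out[0])

    def test_holm_dominates_raw_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        for fn in (lb.bh_adjust, lb.holm_adjust):
            adj = fn(p)
            assert (adj >= p - 1e-12).all()
            assert (adj <= 1.0).all()

    @given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1,
                     max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_dominating(self, p):
        # adjusted p preserve the ordering of the raw p and never shrink
        for fn in (lb.bh_adjust, lb.holm_adjust):
            adj = np.asarray(fn(p))
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert (adj >= np.asarray(p) - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lb.bh_adjust([0.5, 1.2])


class TestKSChi2:
    def test_ks_identical_and_disjoint(self):
        a = np.arange(10.0)
        assert lb.ks_test(a, a).statistic == 0.0
        assert lb.ks_test(a, a + 100.0).statistic == 1.0

    def test_chi2_hand_value_without_correction(self):
        res = lb.chi2_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_chi2_low_expected_warns(self):
        with pytest.warns(UserWarning):
            lb.chi2_test([[2, 1], [1, 2]])


class TestTypeOneCalibration:
    def test_alpha_level_within_band_under_null(self):
        """Each test rejects at ~5% under its own null (2000 replicates)."""
        rng = np.random.default_rng(42)
        n_rep = 2000
        rej = {"friedman": 0, "kruskal": 0, "wilcoxon": 0, "pearson": 0,
               "ks": 0}
        groups = np.repeat([0, 1, 2], 15)
        for _ in range(n_rep):
            rej["friedman"] += (
                lb.friedman_conover(rng.standard_normal((15, 3))).p <= 0.05
            )
            rej["kruskal"] += (
                lb.kruskal_dunn(rng.standard_normal(45), groups).p <= 0.05
            )
            rej["wilcoxon"] += (
                lb.wilcoxon_cc(
                    rng.standard_normal(15), rng.standard_normal(15)
                ).p <= 0.05
            )
            rej["pearson"] += (
                lb.pearson_r(
                    rng.standard_normal(20), rng.standard_normal(20)
                ).p <= 0.05
            )
            rej["ks"] += (
                lb.ks_test(
                    rng.standard_normal(100), rng.standard_normal(100)
                ).p <= 0.05
            )
        for name, hits in rej.items():
            assert 0.03 <= hits / n_rep <= 0.07, (name, hits / n_rep)


class TestInteractionPermutation:
    @staticmethod
    def _long(n_per_group, rng, slopes=(0.0, 0.0), noise=1.0):
        n = 2 * n_per_group
        part = np.repeat(np.arange(n), 3)
        time = np.tile([0.0, 1.0, 2.0], n)
        group_by_part = np.repeat([0, 1], n_per_group)
        group = group_by_part[part]
        slope = np.where(group == 1, slopes[1], slopes[0])
        values = slope * time + noise * rng.standard_normal(len(part))
        return values, group, time, part

    def test_identical_trajectories_p_near_one(self):
        part = np.repeat(np.arange(10), 3)
        time = np.tile([0, 1, 2], 10)
        group = part % 2
        values = np.tile([1.0, 2.0, 3.0], 10) + part * 10.0
        res = lb.group_time_interaction_perm(
            values, group, time, part, n_perm=200, seed=0
        )
        assert res.p > 0.9

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for i in range(150):
            values, group, time, part = self._long(10, rng)
            ps.append(
                lb.group_time_interaction_perm(
                    values, group, time, part, n_perm=199, seed=i
                ).p
            )
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_divergent_slopes_detected(self):
        rng = np.random.default_rng(8)
        values, group, time, part = self._long(
            30, rng, slopes=(-1.0, 1.0), noise=0.5
        )
        res = lb.group_time_interaction_perm(
            values, group, time, part, n_perm=399, seed=1
        )
        assert res.p <= 0.01

    def test_more_than_two_groups_rejected(self):
        part = np.repeat(np.arange(6), 3)
        with pytest.raises(ValueError):
            lb.group_time_interaction_perm(
                np.zeros(18), part % 3, np.tile([0, 1, 2], 6), part,
                n_perm=10, seed=0,
            )
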