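"""Paired differential abundance: fold changes, bias correction, tests,
permutation-subset robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from liftbiome.config import CohortConfig, DaaConfig, MicrobiomeSimConfig
from liftbiome import daa as daa_mod
from liftbiome import simulate as sim


def _toy_counts(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(
        columns, index=[f"ASV{i:04d}" for i in range(1, len(next(iter(columns.values()))) + 1)]
    )


def _meta(samples):
    return pd.DataFrame(
        samples, columns=["sample-id", "participant", "timepoint"]
    ).set_index("sample-id")


class TestPairedLog2FC:
    def test_identical_samples_give_zero(self):
        col = list(np.arange(1, 13))
        counts = _toy_counts({"p-W0": col, "p-W8": col})
        meta = _meta([("p-W0", "p", "W0"), ("p-W8", "p", "W8")])
        cfg = DaaConfig(prevalence_min=0.0)
        fc = daa_mod.paired_log2fc(counts, meta, cfg)
        assert np.allclose(fc.fcs["W8"].to_numpy(), 0.0)

    def test_doubled_count_at_equal_depth_is_one(self):
        base = [1000] + [100] * 11
        follow = [2000] + [100] * 11
        # pad another ASV so depths match exactly
        base += [1100]
        follow += [100]
        counts = _toy_counts({"p-W0": base, "p-W8": follow})
        meta = _meta([("p-W0", "p", "W0"), ("p-W8", "p", "W8")])
        assert sum(base) == sum(follow)
        cfg = DaaConfig(prevalence_min=0.0)
        fc = daa_mod.paired_log2fc(counts, meta, cfg)
        assert fc.fcs["W8"].iloc[0, 0] == pytest.approx(1.0, abs=2e-3)

    def test_zero_to_seven_with_half_pseudocount(self):
        base = [0] + [100] * 10
        follow = [7] + [100] * 10
        counts = _toy_counts({"p-W0": base, "p-W8": follow})
        meta = _meta([("p-W0", "p", "W0"), ("p-W8", "p", "W8")])
        cfg = DaaConfig(prevalence_min=0.0)
        fc = daa_mod.paired_log2fc(counts, meta, cfg)
        expected = np.log2(7.5 / 0.5) - np.log2(1007 / 1000)
        assert fc.fcs["W8"].iloc[0, 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.9069, abs=2e-2)

    def test_participant_without_baseline_skipped(self):
        counts = _toy_counts(
            {"a-W0": [5, 5], "a-W8": [5, 5], "b-W8": [5, 5]}
        )
        meta = _meta(
            [("a-W0", "a", "W0"), ("a-W8", "a", "W8"), ("b-W8", "b", "W8")]
        )
        fc = daa_mod.paired_log2fc(counts, meta, DaaConfig(prevalence_min=0))
        assert fc.skipped == ["b"]
        assert list(fc.fcs["W8"].index) == ["a"]

    def test_prevalence_filter(self):
        counts = _toy_counts(
            {"a-W0": [5, 0], "a-W8": [5, 0], "b-W0": [5, 0], "b-W8": [5, 1]}
        )
        meta = _meta(
            [("a-W0", "a", "W0"), ("a-W8", "a", "W8"),
             ("b-W0", "b", "W0"), ("b-W8", "b", "W8")]
        )
        fc = daa_mod.paired_log2fc(counts, meta,
                                   DaaConfig(prevalence_min=0.5))
        assert fc.asvs == ["ASV0001"]


class TestBiasCorrect:
    def test_constant_shift_removed(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.standard_normal((6, 50)))
        shifted = base + 2.5
        a = daa_mod.bias_correct(base)
        b = daa_mod.bias_correct(shifted)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_median_of_each_row_zero(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.standard_normal((4, 31)))
        centered = daa_mod.bias_correct(frame)
        assert np.allclose(centered.median(axis=1), 0.0)

    def test_planted_shift_survives_centering(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(0.1 * rng.standard_normal((20, 200)))
        frame.iloc[:, 0] += 2.0
        centered = daa_mod.bias_correct(frame)
        assert centered.iloc[:, 0].mean() == pytest.approx(2.0, abs=0.1)

    def test_too_few_asvs_rejected(self):
        with pytest.raises(ValueError):
            daa_mod.bias_correct(pd.DataFrame(np.zeros((3, 5))))

    def test_depth_scaling_invariance(self):
        # multiplying one sample's counts by a constant changes the paired
        # fold changes only through the pseudocount, bounded by ~pc/depth
        rng = np.random.default_rng(3)
        col = rng.integers(50, 500, size=40)
        counts = _toy_counts({"p-W0": col, "p-W8": col * 3})
        meta = _meta([("p-W0", "p", "W0"), ("p-W8", "p", "W8")])
        cfg = DaaConfig(prevalence_min=0.0)
        fc = daa_mod.bias_correct(daa_mod.paired_log2fc(counts, meta, cfg))
        assert np.abs(fc.fcs["W8"].to_numpy()).max() < 0.05


class TestDaaTest:
    def _fc(self, mat):
        frame = pd.DataFrame(
            mat, columns=[f"ASV{i:04d}" for i in range(1, mat.shape[1] + 1)]
        )
        return daa_mod.PairedFoldChanges(fcs={"W8": frame},
                                         asvs=list(frame.columns))

    def test_all_zero_fcs_nothing_significant(self):
        with pytest.warns(UserWarning):
            res = daa_mod.daa_test(self._fc(np.zeros((8, 12))))
        assert not res["significant"].any()
        assert (res["p"] == 1.0).all()

    def test_zero_variance_warns_p_one(self):
        mat = np.zeros((6, 12))
        mat[:, 0] = 2.0  # constant nonzero: zero variance, huge mean
        with pytest.warns(UserWarning):
            res = daa_mod.daa_test(self._fc(mat))
        row = res[res["asv"] == "ASV0001"].iloc[0]
        assert row["p"] == 1.0 and not row["significant"]

    def test_strong_effect_detected_with_holm(self):
        rng = np.random.default_rng(4)
        mat = 0.3 * rng.standard_normal((20, 15))
        mat[:, 2] += 2.0
        frame = pd.DataFrame(
            mat, columns=[f"ASV{i:04d}" for i in range(1, 16)]
        )
        fc = daa_mod.PairedFoldChanges(
            fcs={"W4": frame * 0.5, "W8": frame}, asvs=list(frame.columns)
        )
        res = daa_mod.daa_test(fc)
        w8 = res[(res["contrast"] == "W8") & (res["asv"] == "ASV0003")]
        assert bool(w8["significant"].iloc[0])
        # Holm within ASV matches statsmodels on the two contrasts
        from statsmodels.stats.multitest import multipletests

        for asv, sub in res.groupby("asv"):
            expected = multipletests(sub["p"], method="holm")[1]
            assert np.allclose(sub["holm_p"], expected)

    def test_type_one_error_of_joint_rule_small(self):
        """Global-null simulations: the joint p & fold-change rule fires
        for well under 1% of ASVs (reduced-size version of the full
        acceptance property)."""
        rng_master = np.random.default_rng(5)
        total = hits = 0
        for rep in range(20):
            mat = 0.8 * rng_master.standard_normal((30, 60))
            res = daa_mod.daa_test(self._fc(mat))
            hits += int(res["significant"].sum())
            total += 60
        assert hits / total <= 0.01


class TestEmpiricalP:
    def test_99_of_100_convention(self):
        permuted = list(range(99)) + [150]
        assert daa_mod.empirical_pvalue(100, permuted) == pytest.approx(0.01)

    def test_observed_below_all(self):
        assert daa_mod.empirical_pvalue(1, [5, 6, 7]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            daa_mod.empirical_pvalue(1, [])


@pytest.fixture(scope="module")
def planted_study():
    cohort = sim.generate_cohort(
        CohortConfig(n_enrolled=60, n_dropout=0, n_quality_excluded=0,
                     n_validation_excluded=0, seed=31)
    )
    rng = np.random.default_rng(32)
    scores = pd.Series(
        rng.normal(24, 16, len(cohort)), index=cohort["participant"]
    )
    cfg = MicrobiomeSimConfig(
        n_asv=100, mean_depth=5000, n_planted_up=6, n_planted_down=4,
        seed=33,
    )
    counts, meta, _, truth = sim.generate_asv_tables(cohort, scores, cfg)
    hr = list(scores.sort_values().index[-12:])
    pool = [p for p in scores.index if p not in hr]
    return counts, meta.set_index("sample-id"), truth, hr, pool


class TestPermutationRobustness:

    def test_observed_exceeds_permuted_and_reproducible(self, planted_study):
        counts, meta, truth, hr, pool = planted_study
        a = daa_mod.permutation_robustness(
            counts, meta, hr, pool, n_subsets=25, seed=7
        )
        b = daa_mod.permutation_robustness(
            counts, meta, hr, pool, n_subsets=25, seed=7
        )
        assert a.permuted_n_sig == b.permuted_n_sig
        assert a.empirical_p == b.empirical_p
        assert a.observed_n_sig > np.mean(a.permuted_n_sig)
        assert a.empirical_p <= 0.05

    def test_chance_freq_and_q_structure(self, planted_study):
        counts, meta, truth, hr, pool = planted_study
        summary = daa_mod.permutation_robustness(
            counts, meta, hr, pool, n_subsets=25, seed=7
        )
        assert set(summary.q) == set(summary.observed_asvs)
        for asv in summary.observed_asvs:
            assert summary.q[asv] >= summary.chance_freq[asv] - 1e-12
        # q list is BH-monotone in the chance frequencies
        freqs = [summary.chance_freq[a] for a in summary.observed_asvs]
        qs = [summary.q[a] for a in summary.observed_asvs]
        order = np.argsort(freqs)
        assert (np.diff(np.array(qs)[order]) >= -1e-12).all()

    def test_zero_chance_freq_reported_as_upper_bound(self, planted_study):
        counts, meta, truth, hr, pool = planted_study
        summary = daa_mod.permutation_robustness(
            counts, meta, hr, pool, n_subsets=25, seed=7
        )
        results = daa_mod.run_daa(counts, meta, hr)
        table = daa_mod.fig_table(results, summary)
        zero = [
            a for a in summary.observed_asvs
            if summary.chance_freq[a] == 0.0
        ]
        if zero:
            shown = table.set_index("asv").loc[zero[0], "q"]
            assert shown.startswith("<")

    def test_validation_errors(self, planted_study):
        counts, meta, _, hr, pool = planted_study
        with pytest.raises(ValueError):
            daa_mod.permutation_robustness(counts, meta, hr, hr[:5],
                                           n_subsets=5, seed=0)
        with pytest.raises(ValueError):
            daa_mod.permutation_robustness(counts, meta, hr, pool,
                                           n_subsets=0, seed=0)
        with pytest.raises(ValueError):
            daa_mod.permutation_robustness(
                counts, meta, hr, pool + hr[:1], n_subsets=5, seed=0
            )

    def test_null_empirical_p_valid(self):
        """With no planted effects the HR subset is exchangeable with the
        pool, so the empirical p must be stochastically valid:
        P(p <= alpha) <= ~alpha over replicate simulations.  (The count
        statistic is almost always 0 under the null, so its empirical p
        has a large atom at 1 and cannot be exactly uniform.)"""
        ps = []
        for rep in range(40):
            cohort = sim.generate_cohort(
                CohortConfig(n_enrolled=30, n_dropout=0,
                             n_quality_excluded=0,
                             n_validation_excluded=0, seed=200 + rep)
            )
            cfg = MicrobiomeSimConfig(
                n_asv=40, mean_depth=2000, coupling_strength=0.0,
                effect_log2fc_w4=0.0, effect_log2fc_w8=0.0,
                n_planted_up=3, n_planted_down=2, seed=300 + rep,
            )
            counts, meta, _, _ = sim.generate_asv_tables(cohort, None, cfg)
            ids = list(cohort["participant"])
            hr, pool = ids[:10], ids[10:]
            summary = daa_mod.permutation_robustness(
                counts, meta.set_index("sample-id"), hr, pool,
                n_subsets=20, seed=400 + rep,
            )
            ps.append(summary.empirical_p)
        ps = np.asarray(ps)
        # validity at the tails (binomial slack for 40 replicates)
        assert np.mean(ps <= 0.05) <= 0.15
        assert np.mean(ps <= 0.25) <= 0.40
        # the p never collapses to systematically tiny values
        assert np.median(ps) > 0.25
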