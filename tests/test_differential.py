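import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import splicebalance as sb
from splicebalance.errors import ConfigurationError, DataError
from splicebalance.expression import summarize_gene_expression


class TestEBPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = sb.fit_eb_prior(np.full(100, 2.5), df=10)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.5)

    def test_simulation_recovery(self):
        # s^2 ~ s0^2 * (chi2_df / df) with 1/sigma^2 ~ chi2_d0 / (d0 s0^2)
        rng = np.random.default_rng(0)
        d0, s0_sq, df = 4.0, 1.0, 10
        sigma2 = d0 * s0_sq / rng.chisquare(d0, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        prior = sb.fit_eb_prior(s2, df)
        assert 3.0 <= prior.d0 <= 5.0
        assert 0.9 <= prior.s0_sq <= 1.1

    def test_two_features_fall_back_with_warning(self):
        with pytest.warns(UserWarning):
            prior = sb.fit_eb_prior([1.0, 2.0], df=4)
        assert math.isinf(prior.d0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DataError):
            sb.fit_eb_prior(np.zeros(50), df=4)


class TestModeratedT:
    def test_identical_groups_give_zero_effect_p_one(self):
        row = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        matrix = pd.DataFrame([row, row + 1])
        out = sb.moderated_t_test(matrix, ["a", "a", "a", "b", "b", "b"], prior=None)
        np.testing.assert_allclose(out["effect"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_prior_off_equals_classical_pooled_t(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            na, nb = rng.integers(2, 8, size=2)
            matrix = pd.DataFrame(rng.normal(size=(20, na + nb)))
            labels = ["a"] * na + ["b"] * nb
            out = sb.moderated_t_test(matrix, labels, prior=None, group_order=("a", "b"))
            ref = stats.ttest_ind(
                matrix.iloc[:, :na], matrix.iloc[:, na:], axis=1, equal_var=True
            )
            np.testing.assert_allclose(out["t_mod"], ref.statistic, atol=1e-10)
            np.testing.assert_allclose(out["p"], ref.pvalue, atol=1e-10)

    def test_infinite_prior_uses_s0_exactly(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.normal(size=(30, 10)))
        prior = sb.EBPrior(math.inf, 2.0)
        out = sb.moderated_t_test(
            matrix, ["a"] * 5 + ["b"] * 5, prior=prior, group_order=("a", "b")
        )
        se = math.sqrt(2.0 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(out["t_mod"], out["effect"] / se, atol=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(2000, 20)))
        out = sb.moderated_t_test(matrix, ["a"] * 10 + ["b"] * 10)
        frac = float((out["p"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_small_group_rejected(self):
        matrix = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(DataError):
            sb.moderated_t_test(matrix, ["a", "a", "b"])


class TestBHAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            sb.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_constant(self):
        np.testing.assert_allclose(sb.bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(sb.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            sb.bh_adjust([0.5, 1.2])

    @given(st.integers(0, 2**32 - 1), st.integers(1, 200))
    @settings(max_examples=25, deadline=None)
    def test_matches_statsmodels_and_monotone(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(size=m)
        q = sb.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallGenes:
    def _tables(self, ge_q, si_probe_q, tiny_annotation):
        ge = pd.DataFrame({"q": ge_q}, index=pd.Index(["gA", "gB"], name="gene_id"))
        si = pd.DataFrame(
            {"q": si_probe_q},
            index=pd.Index(
                ["gA:E00", "gA:E01", "gB:E00", "gB:E01", "gB:E02"], name="feature_id"
            ),
        )
        return ge, si

    def test_rule_application(self, tiny_annotation):
        ge, si = self._tables([5e-4, 0.5], [0.5, 0.9, 1e-5, 0.2, 0.3], tiny_annotation)
        calls = sb.call_genes(ge, si, tiny_annotation)
        assert calls.loc["gA", "category"] == "GE_only"
        assert calls.loc["gB", "category"] == "SI_only"

    def test_both_category(self, tiny_annotation):
        ge, si = self._tables([1e-4, 0.7], [1e-4, 0.9, 0.5, 0.2, 0.3], tiny_annotation)
        calls = sb.call_genes(ge, si, tiny_annotation)
        assert calls.loc["gA", "category"] == "both"
        assert calls.loc["gB", "category"] == "neither"

    def test_si_gene_missing_from_ge_rejected(self, tiny_annotation):
        ge = pd.DataFrame({"q": [0.5]}, index=pd.Index(["gA"], name="gene_id"))
        si = pd.DataFrame(
            {"q": [0.5, 0.1, 0.1]},
            index=pd.Index(["gB:E00", "gB:E01", "gB:E02"], name="feature_id"),
        )
        with pytest.raises(DataError):
            sb.call_genes(ge, si, tiny_annotation)


class TestPartitionSummary:
    def test_fraction_arithmetic(self):
        calls = pd.DataFrame(
            {"category": ["GE_only"] * 2 + ["SI_only"] * 3 + ["both"] * 5}
        )
        out = sb.partition_summary(calls)
        np.testing.assert_allclose(
            out.loc[["GE_only", "SI_only", "both"], "fraction_perturbed"],
            [0.2, 0.3, 0.5],
        )
        assert out["count"].sum() == 10

    def test_counts_conserved(self, small_cohort):
        gm = summarize_gene_expression(small_cohort.matrix, small_cohort.annotation, "linear_sum")
        si = sb.compute_splicing_index(small_cohort.matrix, small_cohort.annotation)
        counts = small_cohort.annotation["gene_id"].value_counts()
        si_t = si.loc[small_cohort.annotation["gene_id"].map(counts) >= 2]
        groups = small_cohort.samples["group"]
        ge = sb.moderated_t_test(gm, groups)
        sit = sb.moderated_t_test(si_t, groups)
        calls = sb.call_genes(ge, sit, small_cohort.annotation)
        summary = sb.partition_summary(calls)
        assert summary["count"].sum() == len(calls)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            sb.partition_summary(pd.DataFrame({"category": []}))


class TestNullDiagnostics:
    def test_null_cohort_uniform(self, null_cohort):
        gm = summarize_gene_expression(null_cohort.matrix, null_cohort.annotation, "mean")
        diag = sb.pvalue_null_diagnostics(
            gm, null_cohort.samples["group"], n_permutations=20, seed=5
        )
        assert diag["ks_uniform_p"] > 0.01
        assert 0 <= diag["ks_uniform"] <= 1 and 0 <= diag["ks_perm"] <= 1

    def test_planted_signal_deviates(self, small_cohort, null_cohort):
        gm = summarize_gene_expression(small_cohort.matrix, small_cohort.annotation, "mean")
        diag = sb.pvalue_null_diagnostics(
            gm, small_cohort.samples["group"], n_permutations=20, seed=5
        )
        gm0 = summarize_gene_expression(null_cohort.matrix, null_cohort.annotation, "mean")
        diag0 = sb.pvalue_null_diagnostics(
            gm0, null_cohort.samples["group"], n_permutations=20, seed=5
        )
        assert diag["frac_below"][0.01] > 0.01
        assert diag["ks_uniform"] > diag0["ks_uniform"]

    def test_permutation_pvalues_uniform(self, null_cohort):
        gm = summarize_gene_expression(null_cohort.matrix, null_cohort.annotation, "mean")
        diag = sb.pvalue_null_diagnostics(
            gm, null_cohort.samples["group"], n_permutations=20, seed=6
        )
        rng = np.random.default_rng(7)
        sample = rng.choice(diag["perm_pvalues"], size=1000, replace=False)
        assert stats.kstest(sample, "uniform").pvalue > 0.001

    def test_seed_reproducible(self, null_cohort):
        gm = summarize_gene_expression(null_cohort.matrix, null_cohort.annotation, "mean")
        d1 = sb.pvalue_null_diagnostics(gm, null_cohort.samples["group"], 10, seed=9)
        d2 = sb.pvalue_null_diagnostics(gm, null_cohort.samples["group"], 10, seed=9)
        np.testing.assert_array_equal(d1["perm_pvalues"], d2["perm_pvalues"])

    def test_too_few_permutations_rejected(self, null_cohort):
        with pytest.raises(ConfigurationError):
            sb.pvalue_null_diagnostics(
                null_cohort.matrix, null_cohort.samples["group"], n_permutations=5
            )


class TestPairwiseSimilarity:
    def test_duplicated_sample_r2_one(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=200)
        matrix = pd.DataFrame(
            {"s1": base, "s2": base, "s3": rng.normal(size=200), "s4": rng.normal(size=200)}
        )
        out = sb.pairwise_similarity(matrix, ["g1", "g1", "g2", "g2"])
        # the duplicated pair dominates the within-group mean
        assert out["mean_within_r2"] > out["mean_between_r2"]
        assert out["n_within_pairs"] == 2 and out["n_between_pairs"] == 4

    def test_independent_noise_low_r2(self):
        rng = np.random.default_rng(11)
        matrix = pd.DataFrame(rng.normal(size=(5000, 8)))
        out = sb.pairwise_similarity(matrix, ["a"] * 4 + ["b"] * 4)
        assert out["mean_within_r2"] < 0.01 and out["mean_between_r2"] < 0.01

    def test_planted_structure(self, small_cohort):
        out = sb.pairwise_similarity(small_cohort.matrix, small_cohort.samples["group"])
        assert out["mean_within_r2"] > out["mean_between_r2"]
        assert out["ranksum_p"] < 0.05

    def test_constant_sample_excluded_with_warning(self):
        rng = np.random.default_rng(12)
        matrix = pd.DataFrame(rng.normal(size=(50, 5)))
        matrix.iloc[:, 0] = 1.0
        with pytest.warns(UserWarning):
            out = sb.pairwise_similarity(matrix, ["a", "a", "a", "b", "b"])
        assert out["n_within_pairs"] == 2  # one 'a' dropped
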