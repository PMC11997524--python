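"""Contingency-table and rank statistics for cluster characterization.

2x2 tables below marked "reference cohort" are reconstructed from the
published summary tables of a 3454-patient memory-clinic cohort; the
expected statistics are the values printed alongside them.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cohort_subtyper.stats import (
    EXCLUSIVE,
    ContingencyTable,
    adjust_p,
    adjusted_residuals,
    chi2_2x2_yates,
    chi2_rxc,
    code_enrichment,
    cramers_v,
    cross_tabulate,
    dunn_posthoc,
    kruskal_wallis_eta2,
    prevalence_ratio,
    select_top_codes,
    table_from_adjusted_residuals,
)

# female-in-cluster-3 vs rest, ICD arm of the reference cohort
FEMALE_ICD3 = [[200, 156], [1478, 1620]]
# female-in-cluster-1 vs rest, note arm
FEMALE_NOTE1 = [[812, 468], [866, 1308]]
# FTD-in-cluster-2 vs rest, ICD arm
FTD_ICD2 = [[121, 1476], [69, 1788]]


class TestYatesChi2:
    def test_reference_cohort_sex_tables(self):
        chi2, _ = chi2_2x2_yates(FEMALE_ICD3)
        assert chi2 == pytest.approx(8.8, abs=0.05)
        chi2, _ = chi2_2x2_yates(FEMALE_NOTE1)
        assert chi2 == pytest.approx(178.7, abs=0.05)

    def test_exact_independence_is_zero(self):
        chi2, p = chi2_2x2_yates([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi2_2x2_yates([[0, 5], [0, 7]])

    def test_wrong_shape_raises(self):
        with pytest.raises(ValueError):
            chi2_2x2_yates(np.ones((2, 3), dtype=int))

    @given(
        arrays(np.int64, (2, 2), elements=st.integers(min_value=1, max_value=500))
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_yates_never_exceeds_uncorrected_pearson(self, table):
        corrected, _ = chi2_2x2_yates(table)
        uncorrected, _, _ = chi2_rxc(table)
        assert corrected <= uncorrected + 1e-12


class TestPearsonRxC:
    def test_reference_crosstab_statistic(self):
        table = [[492, 711, 77], [539, 461, 161], [470, 425, 118]]
        chi2, df, p = chi2_rxc(table)
        assert chi2 == pytest.approx(89.43, abs=0.01)
        assert df == 4
        assert p < 0.001

    def test_proportional_rows_give_zero(self):
        chi2, _, _ = chi2_rxc([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_2x2(self):
        # N (ad - bc)^2 / (r1 r2 c1 c2) = 80 * 800^2 / 40^4 = 20
        chi2, df, _ = chi2_rxc([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1


class TestPrevalenceRatio:
    def test_reference_cohort_values(self):
        assert prevalence_ratio(FEMALE_ICD3) == pytest.approx(1.178, abs=5e-4)
        assert prevalence_ratio(FTD_ICD2) == pytest.approx(2.039, abs=5e-4)
        assert prevalence_ratio(FEMALE_NOTE1) == pytest.approx(1.593, abs=5e-4)

    def test_exclusive_flag(self):
        assert prevalence_ratio([[5, 5], [0, 10]]) == EXCLUSIVE

    def test_zero_in_cluster_prevalence(self):
        assert prevalence_ratio([[0, 10], [5, 5]]) == 0.0

    def test_absent_everywhere_raises(self):
        with pytest.raises(ValueError):
            prevalence_ratio([[0, 10], [0, 10]])


class TestAdjustP:
    def test_bonferroni(self):
        assert adjust_p([0.01, 0.5], "bonferroni").tolist() == [0.02, 1.0]

    def test_bh_step_up_hand_case(self):
        out = adjust_p([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert adjust_p([0.37], "bh").tolist() == [0.37]
        assert adjust_p([0.37], "bonferroni").tolist() == [0.37]

    def test_order_restored(self):
        ps = [0.9, 0.001, 0.5]
        out = adjust_p(ps, "bh")
        assert np.argmin(out) == 1

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bh_never_exceeds_bonferroni(self, ps):
        bh = adjust_p(ps, "bh")
        bonf = adjust_p(ps, "bonferroni")
        assert np.all(bh <= bonf + 1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust_p([1.5], "bh")


class TestKruskalWallis:
    def test_eta_squared_from_reference_H(self):
        # formula check at the reference cohort's size: (H - k + 1)/(N - k)
        assert (182.6 - 3 + 1) / (3454 - 3) == pytest.approx(0.052, abs=5e-4)
        assert (14.9 - 3 + 1) / (3454 - 3) == pytest.approx(0.004, abs=5e-4)

    def test_hand_rank_computation_no_ties(self):
        values = np.arange(1.0, 10.0)
        groups = np.repeat([0, 1, 2], 3)
        res = kruskal_wallis_eta2(values, groups)
        assert res.H == pytest.approx(7.2, abs=1e-9)
        assert res.df == 2
        assert res.eta_squared == pytest.approx((7.2 - 2) / 6)

    def test_constant_values_warn_and_zero(self, caplog):
        with caplog.at_level("WARNING"):
            res = kruskal_wallis_eta2(np.ones(10), np.repeat([0, 1], 5))
        assert res.H == 0.0

    def test_group_sanity(self):
        with pytest.raises(ValueError):
            kruskal_wallis_eta2([1.0, 2.0], [0, 0])


class TestDunn:
    def test_hand_z_statistic(self):
        values = np.arange(1.0, 10.0)
        groups = np.repeat([0, 1, 2], 3)
        out = dunn_posthoc(values, groups)
        z13 = out[(out.group_a == 0) & (out.group_b == 2)].z.item()
        assert z13 == pytest.approx(-6 / np.sqrt(5), abs=1e-9)

    def test_identical_groups_zero(self):
        values = np.tile([1.0, 2.0, 3.0], 2)
        out = dunn_posthoc(values, np.repeat([0, 1], 3))
        assert out.z.abs().max() == pytest.approx(0.0)

    def test_sign_antisymmetry_under_relabeling(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=30)
        groups = np.repeat([0, 1], 15)
        z_ab = dunn_posthoc(values, groups).z.item()
        z_ba = dunn_posthoc(values, 1 - groups).z.item()
        assert z_ab == pytest.approx(-z_ba)


class TestCrossTab:
    def test_reference_crosstab_v_and_residuals(self):
        counts = np.array([[492, 711, 77], [539, 461, 161], [470, 425, 118]])
        chi2, _, _ = chi2_rxc(counts)
        assert cramers_v(chi2, counts.sum(), counts.shape) == pytest.approx(0.114, abs=5e-4)
        resid = adjusted_residuals(counts)
        assert resid[0, 1] == pytest.approx(8.42, abs=0.01)
        assert resid[1, 2] == pytest.approx(4.90, abs=0.01)
        assert resid[0, 0] == pytest.approx(-4.57, abs=0.01)

    def test_independent_table_zero_residuals(self):
        counts = np.outer([10, 20], [5, 15, 30])
        assert np.allclose(adjusted_residuals(counts), 0.0)

    def test_identical_labelings_perfect_association(self):
        labels = np.repeat([0, 1, 2], 20)
        report = cross_tabulate(labels, labels)
        assert report.cramers_v == pytest.approx(1.0)

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_tabulate([0, 1], [0, 1, 2])


class TestTableReconstruction:
    ROWS = [1280, 1161, 1013]
    COLS = [1501, 1597, 356]
    RESIDUALS = {
        (0, 0): -4.57, (0, 1): 8.42, (0, 2): -6.36,
        (1, 1): -5.48, (1, 2): 4.90,
        (2, 1): -3.25,
    }

    def test_reconstruction_reproduces_published_statistic(self):
        table = table_from_adjusted_residuals(self.ROWS, self.COLS, self.RESIDUALS)
        assert table.tolist() == [[492, 711, 77], [539, 461, 161], [470, 425, 118]]
        chi2, df, _ = chi2_rxc(table)
        assert chi2 == pytest.approx(89.43, abs=0.01)

    def test_residual_convention_round_trips(self):
        # inverting then recomputing recovers every given residual: the
        # consistency check that pins down the ADJUSTED residual convention
        table = table_from_adjusted_residuals(self.ROWS, self.COLS, self.RESIDUALS)
        resid = adjusted_residuals(table)
        for (i, j), r in self.RESIDUALS.items():
            assert resid[i, j] == pytest.approx(r, abs=0.01)

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError, match="underdetermine"):
            table_from_adjusted_residuals(self.ROWS, self.COLS, {(0, 0): -4.57})

    def test_marginal_mismatch_raises(self):
        with pytest.raises(ValueError):
            table_from_adjusted_residuals([10, 10], [5, 5, 5], {})


class TestCodeEnrichment:
    def _planted(self, rng, frac_in=0.8, frac_out=0.1):
        n = 300
        labels = np.repeat([0, 1, 2], n // 3)
        marker = np.where(
            labels == 1, rng.random(n) < frac_in, rng.random(n) < frac_out
        ).astype(int)
        noise = (rng.random(n) < 0.5).astype(int)
        presence = pd.DataFrame({"marker": marker, "noise": noise})
        return presence, labels

    def test_planted_feature_ranks_first_with_expected_pr(self, rng):
        presence, labels = self._planted(rng)
        results = [r for r in code_enrichment(presence, labels) if r.cluster == 1]
        top = select_top_codes(results)
        assert top[0].feature == "marker"
        assert top[0].prevalence_ratio == pytest.approx(8.0, rel=0.25)
        assert top[0].p_adjusted < 0.05

    def test_uniform_feature_not_significant(self, rng):
        n = 300
        labels = np.repeat([0, 1, 2], n // 3)
        presence = pd.DataFrame({"flat": np.tile([0, 1], n // 2)})
        results = code_enrichment(presence, labels)
        assert all(r.p_adjusted > 0.5 for r in results)

    def test_absent_feature_skipped(self, rng, caplog):
        presence = pd.DataFrame({"gone": np.zeros(30, dtype=int), "ok": np.tile([0, 1], 15)})
        with caplog.at_level("WARNING"):
            results = code_enrichment(presence, np.repeat([0, 1], 15))
        assert {r.feature for r in results} == {"ok"}


class TestSelectTopCodes:
    def _make(self, feature, p_adj, pr, cluster=0):
        from cohort_subtyper.stats import EnrichmentResult

        return EnrichmentResult(feature, cluster, 1.0, 1, p_adj, p_adj, pr, (1, 1, 1, 1))

    def test_caps_at_n_significant_by_pr(self):
        results = [self._make(f"f{i}", 0.01, float(i)) for i in range(12)]
        top = select_top_codes(results, n=10)
        assert len(top) == 10
        assert top[0].feature == "f11"

    def test_falls_back_to_nonsignificant(self):
        results = [self._make("a", 0.9, 4.65), self._make("b", 0.99, 2.0)]
        top = select_top_codes(results)
        assert [r.feature for r in top] == ["a", "b"]
        assert all(not r.significant for r in top)

    def test_exclusive_outranks_finite_pr(self):
        results = [self._make("a", 0.01, 3.0), self._make("b", 0.01, EXCLUSIVE)]
        assert select_top_codes(results)[0].feature == "b"

    def test_exactly_the_significant_ones(self):
        results = [self._make(f"f{i}", 0.01, 2.0) for i in range(3)] + [
            self._make("ns", 0.5, 9.0)
        ]
        top = select_top_codes(results)
        assert len(top) == 3
        assert all(r.feature != "ns" for r in top)

    def test_empty_input(self):
        assert select_top_codes([]) == []
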