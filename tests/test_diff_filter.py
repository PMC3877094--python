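"""Group-wise comparison filter: pairwise stats, queries, invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import betainc

from ifnsig import SimulationConfig, simulate_cohort
from ifnsig.diff_filter import (
    FilterConfig,
    GroupComparisonStats,
    INCREASE_CALLS,
    QueryClause,
    apply_query_filter,
    pairwise_compare,
    run_group_filter,
    summarize_group_stats,
)


def make_stats(**overrides):
    base = dict(
        probeset_id="p1", n_pairs=16, pct_present_a=1.0, pct_present_b=1.0,
        pct_increase=0.0, pct_decrease=0.0, mean_log2fc=0.0, t_p=1.0,
        bonf_p=1.0, max_signal=8.0,
    )
    base.update(overrides)
    return GroupComparisonStats(**base)


class TestPairwiseCompare:
    @pytest.mark.parametrize("na,nb,expected", [(4, 4, 16), (1, 1, 1), (3, 4, 12)])
    def test_comparison_count_is_product_of_group_sizes(
        self, small_cohort, na, nb, expected
    ):
        a = small_cohort.groups["disease"][:na]
        b = (small_cohort.groups["baseline"] * 2)[:nb]
        out = pairwise_compare(a, b)
        assert all(len(v) == expected for v in out.values())

    def test_mismatched_universes_rejected(self, small_cohort):
        import copy

        a = small_cohort.groups["disease"][:1]
        b = [copy.deepcopy(small_cohort.groups["baseline"][0])]
        del b[0].probesets[sorted(b[0].probesets)[0]]
        with pytest.raises(ValueError):
            pairwise_compare(a, b)


class TestSummarize:
    def test_t_test_against_independent_beta_form(self):
        changes = [
            dataclasses.replace(c, slr=v)
            for c, v in zip(_dummy_changes(4), [1.0, 1.0, 1.0, 2.0])
        ]
        st_ = summarize_group_stats("p", changes, ["P"] * 4, ["P"] * 4, 8.0, 7.0, 1)
        assert st_.mean_log2fc == pytest.approx(1.25)
        # closed form: two-sided p = I_{df/(df+t^2)}(df/2, 1/2), t = 5, df = 3
        t = 5.0
        p_closed = betainc(1.5, 0.5, 3 / (3 + t ** 2))
        assert st_.t_p == pytest.approx(p_closed, rel=1e-10)
        assert st_.t_p == pytest.approx(0.01539, abs=5e-5)

    def test_symmetric_slrs_give_p_one(self):
        changes = [dataclasses.replace(c, slr=v) for c, v in zip(_dummy_changes(2), [-1.0, 1.0])]
        st_ = summarize_group_stats("p", changes, ["P"], ["P"], 8.0, 8.0, 1)
        assert st_.t_p == 1.0

    def test_bonferroni_is_min_of_one_and_product(self):
        changes = [dataclasses.replace(c, slr=v) for c, v in
                   zip(_dummy_changes(4), [1.0, 1.01, 0.99, 1.0])]
        st_ = summarize_group_stats("p", changes, ["P"], ["P"], 8.0, 8.0, 100)
        assert st_.bonf_p == pytest.approx(min(1.0, st_.t_p * 100))

    def test_single_pair_reports_warning_p_one(self):
        st_ = summarize_group_stats("p", _dummy_changes(1), ["P"], ["P"], 8.0, 8.0, 1)
        assert st_.t_p == 1.0 and st_.t_warning


def _dummy_changes(n):
    from ifnsig.mas5_lite import ChangeResult

    return [ChangeResult("p", 0.5, "NC", 0.0) for _ in range(n)]


class TestQueryFilter:
    def test_homogeneous_increase(self):
        s = make_stats(pct_increase=0.40, bonf_p=0.01, mean_log2fc=1.2)
        assert apply_query_filter(s, FilterConfig(), True).category == "increased_homogeneous"

    def test_heterogeneous_increase_ignores_p(self):
        s = make_stats(pct_increase=0.60, bonf_p=0.9, mean_log2fc=0.5)
        assert apply_query_filter(s, FilterConfig(), True).category == "increased_heterogeneous"

    def test_below_both_thresholds_not_significant(self):
        s = make_stats(pct_increase=0.20, pct_decrease=0.10, mean_log2fc=0.3)
        lab = apply_query_filter(s, FilterConfig(), True)
        assert lab.category == "not_significant" and lab.passed_present_gate

    def test_failed_gate_blocks_everything(self):
        s = make_stats(pct_increase=0.9, bonf_p=0.001, mean_log2fc=2.0)
        lab = apply_query_filter(s, FilterConfig(), False)
        assert lab.category == "not_significant" and not lab.passed_present_gate

    def test_custom_query_clause(self):
        s = make_stats(pct_increase=0.25, mean_log2fc=3.0)
        cfg = FilterConfig(extra_queries=(
            QueryClause((("mean_log2fc", ">=", 2.5),), label="big_fc"),
        ))
        assert apply_query_filter(s, cfg, True).category == "big_fc"

    @given(
        pct_inc=st.floats(0, 1),
        split=st.floats(0, 1),
        bonf=st.floats(0, 1),
        fc=st.floats(-4, 4),
    )
    @settings(max_examples=300, deadline=None)
    def test_exclusivity_and_swap_symmetry(self, pct_inc, split, bonf, fc):
        pct_dec = (1 - pct_inc) * split
        s = make_stats(pct_increase=pct_inc, pct_decrease=pct_dec,
                       bonf_p=bonf, mean_log2fc=fc)
        cat = apply_query_filter(s, FilterConfig(), True).category
        assert not (cat.startswith("increased") and cat.startswith("decreased"))
        mirrored = make_stats(pct_increase=pct_dec, pct_decrease=pct_inc,
                              bonf_p=bonf, mean_log2fc=-fc)
        cat_m = apply_query_filter(mirrored, FilterConfig(), True).category
        swap = {"increased": "decreased", "decreased": "increased"}
        expected = cat
        for k, v in swap.items():
            if cat.startswith(k):
                expected = v + cat[len(k):]
                break
        assert cat_m == expected

    @given(
        pct_inc=st.floats(0, 1), bonf=st.floats(0, 1), fc=st.floats(-4, 4),
        a1=st.floats(0.001, 0.5), a2=st.floats(0.001, 0.5),
    )
    @settings(max_examples=300, deadline=None)
    def test_nestedness_in_alpha(self, pct_inc, bonf, fc, a1, a2):
        lo, hi = sorted((a1, a2))
        s = make_stats(pct_increase=pct_inc, bonf_p=bonf, mean_log2fc=fc)
        cat_lo = apply_query_filter(s, FilterConfig(alpha_bonf=lo), True).category
        cat_hi = apply_query_filter(s, FilterConfig(alpha_bonf=hi), True).category
        if cat_lo != "not_significant":
            assert cat_hi != "not_significant"


class TestRunGroupFilter:
    def test_recovers_planted_genes_with_bonferroni_bounded_fps(self):
        """50 planted 8-fold genes among 950 nulls, 4 vs 4 arrays."""
        cfg = SimulationConfig(
            n_common=0, n_disease_specific=50, n_immunisation_specific=0,
            n_non_ifn_de=0, n_null=950, n_absent=0,
            disease_fc_mean=3.0, disease_fc_sd=1e-9, noise_sd=0.3,
            two_probeset_frac=0.0, decoy_frac=0.0,
        )
        cohort = simulate_cohort(cfg, seed=1)
        sig, table = run_group_filter(
            cohort.groups["disease"], cohort.groups["baseline"], FilterConfig()
        )
        true = cohort.truth.probesets_of_class("disease_specific")
        assert true <= set(sig)
        assert len(set(sig) - true) <= 5

    def test_identical_groups_yield_empty_set(self, small_cohort):
        g = small_cohort.groups["baseline"]
        sig, _ = run_group_filter(g, g, FilterConfig())
        assert sig == []

    def test_unsatisfiable_thresholds_yield_empty_set(self, small_cohort):
        cfg = FilterConfig(alpha_bonf=0.0, heterog_call_frac=1.01)
        sig, _ = run_group_filter(
            small_cohort.groups["disease"], small_cohort.groups["baseline"], cfg
        )
        assert sig == []

    def test_swap_symmetry_of_groups(self, small_cohort):
        a, b = small_cohort.groups["disease"], small_cohort.groups["baseline"]
        _, fwd = run_group_filter(a, b, FilterConfig())
        _, rev = run_group_filter(b, a, FilterConfig())
        fwd = fwd.set_index("probeset_id").sort_index()
        rev = rev.set_index("probeset_id").sort_index()
        np.testing.assert_allclose(fwd.mean_log2fc, -rev.mean_log2fc, atol=1e-12)
        np.testing.assert_allclose(fwd.pct_increase, rev.pct_decrease, atol=1e-12)
        swap = {"increased": "decreased", "decreased": "increased"}
        for pid in fwd.index:
            c1, c2 = fwd.at[pid, "category"], rev.at[pid, "category"]
            expected = c1
            for k, v in swap.items():
                if c1.startswith(k):
                    expected = v + c1[len(k):]
                    break
            assert c2 == expected

    def test_nestedness_in_alpha_full_filter(self, small_cohort):
        a, b = small_cohort.groups["disease"], small_cohort.groups["baseline"]
        sig_tight, _ = run_group_filter(a, b, FilterConfig(alpha_bonf=0.001))
        sig_loose, _ = run_group_filter(a, b, FilterConfig(alpha_bonf=0.2))
        assert set(sig_tight) <= set(sig_loose)

    def test_bonferroni_conservation_and_sorting(self, small_cohort):
        a, b = small_cohort.groups["disease"], small_cohort.groups["baseline"]
        _, table = run_group_filter(a, b, FilterConfig())
        m = int(table.passed_present_gate.sum())
        np.testing.assert_allclose(
            table.bonf_p, np.minimum(1.0, table.t_p * m), atol=1e-12
        )
        fcs = table.mean_log2fc.abs().to_numpy()
        assert (np.diff(fcs) <= 1e-12).all()
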