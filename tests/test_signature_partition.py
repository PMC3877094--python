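"""Reference intersection, fold-change cutoffs and the signature partition."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifnsig.reference_signature import Annotation
from ifnsig.signature_partition import (
    ConditionResult,
    apply_fc_cutoff,
    intersect_with_reference,
    linear_fc,
    partition_signatures,
    percent,
    summarize_fc_dominance,
    top_candidates,
)


class TestLinearFc:
    @pytest.mark.parametrize("log2fc,expected", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0)])
    def test_signed_reciprocal_convention(self, log2fc, expected):
        assert linear_fc(log2fc) == pytest.approx(expected)

    @given(st.floats(-10, 10))
    @settings(max_examples=100, deadline=None)
    def test_no_values_in_open_unit_interval(self, x):
        assert abs(linear_fc(x)) >= 1.0


class TestIntersectWithReference:
    def test_share_of_significant_list_prints_one_decimal(self):
        all_sig = {f"p{i}" for i in range(3610)}
        ref = {f"p{i}" for i in range(748)}
        ifn, pct = intersect_with_reference(all_sig, ref)
        assert len(ifn) == 748
        assert pct == 20.7

    def test_total_overlap_is_100(self):
        ifn, pct = intersect_with_reference({"a", "b"}, {"a", "b", "c"})
        assert pct == 100.0

    def test_disjoint_is_zero(self):
        assert intersect_with_reference({"a"}, {"b"})[1] == 0.0

    def test_empty_significant_reports_zero_with_warning(self, caplog):
        ifn, pct = intersect_with_reference(set(), {"a"})
        assert (ifn, pct) == (set(), 0.0)


class TestFcCutoff:
    def test_boundary_inclusive_both_signs(self):
        fc = {"up": 2.0, "down": -2.0, "near": 1.99, "neg_near": -1.99}
        assert apply_fc_cutoff(fc, fc, cutoff=2.0) == {"up", "down"}

    def test_constructed_top_count(self):
        fc = {f"p{i}": (4.0 if i < 220 else 1.5) for i in range(748)}
        assert len(apply_fc_cutoff(fc, fc, cutoff=2.0)) == 220

    def test_cutoff_below_one_rejected(self):
        with pytest.raises(ValueError):
            apply_fc_cutoff({"a"}, {"a": 3.0}, cutoff=0.5)

    @given(cut1=st.floats(1, 8), cut2=st.floats(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_raising_cutoff_never_enlarges_top(self, cut1, cut2):
        lo, hi = sorted((cut1, cut2))
        fc = {f"p{i}": v for i, v in enumerate([-9.5, -3.0, -1.2, 1.0, 2.5, 4.0, 7.7])}
        assert apply_fc_cutoff(fc, fc, hi) <= apply_fc_cutoff(fc, fc, lo)


def condition(name, all_sig, top, fc):
    return ConditionResult(
        condition_name=name,
        all_significant=set(all_sig),
        ifn_significant=set(top) | (set(all_sig) & set(top)),
        top=set(top),
        fc={p: fc.get(p, 3.0) for p in all_sig},
    )


def annotation_for(gene_of):
    if not gene_of:
        return None
    return Annotation(
        pd.DataFrame(
            {
                "probeset_id": list(gene_of),
                "gene_symbol": [gene_of[p] for p in gene_of],
                "platform_id": "P1",
            }
        )
    )


def brute_force_partition(x, y, gene_of):
    """Independent re-derivation of the partition from its definitions."""
    common = (x.top & y.all_significant) | (y.top & x.all_significant)
    xs = x.top - y.all_significant
    ys = y.top - x.all_significant
    moved = set()
    for g in {gene_of.get(p, p) for p in common | xs | ys}:
        owned = {p for p in common | xs | ys if gene_of.get(p, p) == g}
        classes = [bool(owned & s) for s in (common, xs, ys)]
        if sum(classes) > 1:
            moved |= owned & (xs | ys)
    return common | moved, xs - moved, ys - moved, moved


class TestPartition:
    def test_gene_straddling_classes_is_pulled_into_common(self):
        # gene G owns p1 (common) and p2 (x-specific): both must end common
        x = condition("x", {"p1", "p2"}, {"p1", "p2"}, {})
        y = condition("y", {"p1"}, {"p1"}, {})
        ann = annotation_for({"p1": "G", "p2": "G"})
        part = partition_signatures(x, y, ann)
        assert part.common == {"p1", "p2"}
        assert part.x_specific == set()
        assert part.reassigned == {"p2"}

    def test_empty_other_condition_makes_all_top_specific(self):
        x = condition("x", {"p1", "p2", "p3"}, {"p1", "p2"}, {})
        y = condition("y", set(), set(), {})
        part = partition_signatures(x, y, annotation_for({}))
        assert part.common == set()
        assert part.x_specific == {"p1", "p2"}

    def test_partition_matches_brute_force_on_toy_universe(self):
        # 8 probe-sets over 5 genes covering every membership combination
        gene_of = {
            "a1": "GA", "a2": "GA", "b1": "GB", "c1": "GC", "c2": "GC",
            "d1": "GD", "e1": "GE", "e2": "GE",
        }
        ann = annotation_for(gene_of)
        universe = list(gene_of)
        for x_top_mask, y_top_mask in itertools.islice(
            itertools.product(range(256), repeat=2), 0, None, 97
        ):
            x_top = {p for i, p in enumerate(universe) if x_top_mask >> i & 1}
            y_top = {p for i, p in enumerate(universe) if y_top_mask >> i & 1}
            x = condition("x", set(universe[:6]) | x_top, x_top, {})
            y = condition("y", set(universe[2:]) | y_top, y_top, {})
            part = partition_signatures(x, y, ann)
            common, xs, ys, moved = brute_force_partition(x, y, gene_of)
            assert (part.common, part.x_specific, part.y_specific, part.reassigned) == (
                common, xs, ys, moved,
            )
            # conservation and disjointness
            assert part.common | part.x_specific | part.y_specific == (
                (x.top & y.all_significant) | (y.top & x.all_significant)
                | (x.top - y.all_significant) | (y.top - x.all_significant)
            )
            assert not part.common & part.x_specific
            assert not part.common & part.y_specific
            assert not part.x_specific & part.y_specific

    def test_swapping_conditions_swaps_specific_sets(self):
        gene_of = {f"p{i}": f"G{i}" for i in range(6)}
        x = condition("x", {"p0", "p1", "p2", "p3"}, {"p0", "p1"}, {})
        y = condition("y", {"p1", "p4", "p5"}, {"p4", "p1"}, {})
        ann = annotation_for(gene_of)
        fwd = partition_signatures(x, y, ann)
        rev = partition_signatures(y, x, ann)
        assert fwd.common == rev.common
        assert fwd.x_specific == rev.y_specific
        assert fwd.y_specific == rev.x_specific

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_disjointness_and_conservation_on_random_universes(self, data):
        n = 8
        universe = [f"p{i}" for i in range(n)]
        gene_of = {p: f"G{data.draw(st.integers(0, 4))}" for p in universe}
        draw_set = lambda: {p for p in universe if data.draw(st.booleans())}
        x_all, y_all = draw_set(), draw_set()
        x_top = {p for p in draw_set() if p in x_all}
        y_top = {p for p in draw_set() if p in y_all}
        x = condition("x", x_all, x_top, {})
        y = condition("y", y_all, y_top, {})
        ann = annotation_for(gene_of)
        part = partition_signatures(x, y, ann)
        ref = brute_force_partition(x, y, gene_of)
        assert (part.common, part.x_specific, part.y_specific, part.reassigned) == ref
        total = part.common | part.x_specific | part.y_specific
        assert len(total) == len(part.common) + len(part.x_specific) + len(part.y_specific)


class TestDominance:
    def test_printed_dominance_fixture(self):
        ids = [f"p{i}" for i in range(94)]
        fc_x = {p: (5.0 if i < 76 else 2.0) for i, p in enumerate(ids)}
        fc_y = {p: 3.0 for p in ids}
        count, pct = summarize_fc_dominance(ids, fc_x, fc_y)
        assert (count, pct) == (76, 81)

    def test_equal_magnitudes_do_not_dominate(self):
        ids = ["a", "b"]
        fc = {"a": 2.0, "b": -3.0}
        assert summarize_fc_dominance(ids, fc, fc) == (0, 0)

    def test_full_dominance_is_100(self):
        ids = ["a", "b"]
        count, pct = summarize_fc_dominance(ids, {"a": 4.0, "b": -9.0}, {"a": 2.0, "b": 3.0})
        assert (count, pct) == (2, 100)

    def test_empty_set_reports_zero(self):
        assert summarize_fc_dominance(set(), {}, {}) == (0, 0.0)


class TestTopCandidates:
    def test_strongest_anchor_fc_ranks_first_and_ns_fills_gaps(self):
        tables = {
            "cd16pos": {"ps_siglec": 165.0, "ps_mid": 12.0, "ps_low": 3.9},
            "cd4": {"ps_mid": 4.0},
        }
        out = top_candidates(tables, anchor="cd16pos", threshold=10.0)
        assert list(out.probeset_id) == ["ps_siglec", "ps_mid"]
        assert out.iloc[0]["fc_cd4"] == "NS"

    def test_below_threshold_excluded(self):
        out = top_candidates({"c": {"p": 3.9}}, anchor="c", threshold=4.0)
        assert out.empty

    def test_all_below_threshold_gives_empty_table(self):
        out = top_candidates({"c": {"p": 1.2, "q": -2.0}}, anchor="c", threshold=10.0)
        assert len(out) == 0


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (191, 393, 1, 48.6), (540, 1534, 1, 35.2), (542, 1775, 1, 30.5),
            (748, 3610, 1, 20.7), (1534, 4222, 0, 36), (1775, 3785, 0, 47),
            (120, 165, 0, 73), (145, 173, 0, 84),
        ],
    )
    def test_printed_table_percentages(self, num, den, decimals, expected):
        assert percent(num, den, decimals) == expected
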