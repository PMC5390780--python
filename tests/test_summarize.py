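from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pretrnaseq import (
    CategoryCounts,
    end_processed_shares,
    mapping_qc,
    processing_efficiency,
    table1_percentages,
    tabulate,
)
from pretrnaseq.classify import Category, ThreePrimeCall
from pretrnaseq.summarize import CATEGORY_ORDER, END_PROCESSED_ORDER


def _cc(counts, gene="tX", lib="L"):
    return CategoryCounts(gene, lib, {Category(k): v for k, v in counts.items()})


def _call(gene, cat, count, intron=True):
    return ThreePrimeCall(
        gene_id=gene, end_offset=0, non_templated_suffix="",
        intron_containing=intron, category=Category(cat), count=count,
    )


class TestTabulate:
    def test_weighted_aggregation(self):
        calls = [_call("tL", "PLUS_CCA", 3), _call("tL", "TRAILER", 5)]
        (cc,) = tabulate(calls, "L")
        assert cc.counts == {Category.PLUS_CCA: 3, Category.TRAILER: 5}
        assert cc.total_assigned == 8

    def test_empty(self):
        assert tabulate([], "L") == []

    def test_two_genes_conserved(self):
        calls = [_call("a", "TRAILER", 2), _call("b", "TRIMMED", 7)]
        out = tabulate(calls, "L")
        assert [cc.gene_id for cc in out] == ["a", "b"]
        assert sum(cc.total_assigned for cc in out) == 9

    def test_intron_only_filter(self):
        calls = [_call("a", "TRAILER", 2, intron=True),
                 _call("a", "TRIMMED", 7, intron=False)]
        (cc,) = tabulate(calls, "L", intron_only=True)
        assert cc.total_assigned == 2


class TestTable1Percentages:
    def test_simple(self):
        pct = table1_percentages(_cc({"PLUS_CCA": 44, "TRAILER": 56}))
        assert pct[Category.PLUS_CCA] == pytest.approx(44.0)

    def test_single_category(self):
        pct = table1_percentages(_cc({"OLIGO_A": 1}))
        assert pct[Category.OLIGO_A] == pytest.approx(100.0)

    def test_partition_sums_to_100(self):
        cc = _cc({c.value: i + 1 for i, c in enumerate(CATEGORY_ORDER)})
        assert sum(table1_percentages(cc).values()) == pytest.approx(100, abs=0.05)

    def test_empty_gene_is_nan(self):
        assert all(math.isnan(v) for v in table1_percentages(_cc({})).values())


class TestEndProcessedShares:
    def test_published_arithmetic_examples(self):
        # renormalizing tabulated per-gene percentages of the four
        # end-processed forms reproduces the printed shares
        shares = end_processed_shares(
            {Category.PLUS_C: 7.6, Category.PLUS_CC: 36.9,
             Category.PLUS_CCA: 12.9, Category.PROCESSED_EXACT: 0.6}
        )
        assert round(shares[Category.PLUS_CCA]) == 22
        shares = end_processed_shares(
            {Category.PLUS_C: 5.6, Category.PLUS_CC: 2.9,
             Category.PLUS_CCA: 4.5, Category.PROCESSED_EXACT: 0.9}
        )
        assert round(shares[Category.PLUS_CCA]) == 32

    def test_single_nonzero(self):
        shares = end_processed_shares({Category.PLUS_CC: 5.0})
        assert shares[Category.PLUS_CC] == pytest.approx(100.0)

    def test_all_zero_is_nan(self):
        assert all(math.isnan(v) for v in end_processed_shares({}).values())

    @given(
        counts=st.lists(
            st.integers(min_value=0, max_value=10**6), min_size=4, max_size=4
        ).filter(lambda v: sum(v) > 0),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, counts, scale):
        raw = dict(zip(END_PROCESSED_ORDER, map(float, counts)))
        scaled = {k: v * scale for k, v in raw.items()}
        a, b = end_processed_shares(raw), end_processed_shares(scaled)
        for cat in END_PROCESSED_ORDER:
            assert a[cat] == pytest.approx(b[cat], abs=1e-9)
        assert sum(a.values()) == pytest.approx(100, abs=1e-9)

    def test_monotonic_in_cca(self):
        base = {Category.PROCESSED_EXACT: 10.0, Category.PLUS_C: 5.0,
                Category.PLUS_CC: 5.0, Category.PLUS_CCA: 5.0}
        s0 = end_processed_shares(base)[Category.PLUS_CCA]
        base[Category.PLUS_CCA] += 5.0
        assert end_processed_shares(base)[Category.PLUS_CCA] > s0


class TestProcessingEfficiency:
    def test_trailer_dominated(self):
        eff = processing_efficiency(
            _cc({"TRAILER": 85, "PLUS_CCA": 3, "PROCESSED_EXACT": 12})
        )
        assert eff["trailer_containing"] == pytest.approx(0.85)
        assert eff["end_processed"] == pytest.approx(0.15)

    def test_all_trimmed(self):
        eff = processing_efficiency(_cc({"TRIMMED": 10}))
        assert eff["trimmed"] == pytest.approx(1.0)

    def test_fractions_sum_to_at_most_one(self):
        eff = processing_efficiency(
            _cc({"TRAILER": 5, "OLIGO_A": 3, "OTHER": 2, "PLUS_C": 1})
        )
        assert sum(eff.values()) == pytest.approx(1.0)


class TestMappingQC:
    def test_above_expectation(self):
        qc = mapping_qc(100, 97, 0)
        assert qc.assigned_fraction == pytest.approx(0.97)
        assert not qc.below_expectation

    def test_below_expectation_warns_not_fails(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, "pretrnaseq.summarize"):
            qc = mapping_qc(100, 90, 0)
        assert qc.below_expectation
        assert any("96" in r.message for r in caplog.records)

    def test_empty(self):
        assert math.isnan(mapping_qc(0, 0, 0).assigned_fraction)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            mapping_qc(10, 9, 2)
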