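"""Venn partition, overlap rates, association and KS tests, quantile binning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xconcord.models import ConcordanceRecord, GeneExpression, ProteinCalls
from xconcord.concordance import (
    ContingencyTable2x2,
    association_test,
    bin_overlap,
    build_table,
    contingency_rna_protein,
    expression_cdf_by_group,
    ks_one_sided,
    overlap_summary,
    venn,
)


def rec(gene_id, ihc, if_, rna, rpkm=1.0, **kw):
    return ConcordanceRecord(gene_id, ihc, if_, rna, rpkm, **kw)


class TestBuildTable:
    def test_missing_expression_becomes_rna_absent(self):
        expr = [GeneExpression("G1", 3, 5.0), GeneExpression("G2", 0, 0.0)]
        calls = [ProteinCalls(f"G{i}", f"AB{i}", True, False) for i in (1, 2, 3)]
        records = build_table(expr, calls)
        assert len(records) == 3
        by = {r.gene_id: r for r in records}
        assert by["G1"].rna_present and by["G1"].rpkm == 5.0
        assert not by["G3"].rna_present and by["G3"].rpkm == 0.0

    def test_empty_calls_and_duplicates(self):
        assert build_table([GeneExpression("G", 1, 1.0)], []) == []
        dup = [ProteinCalls("G", "A1", True, True), ProteinCalls("G", "A2", True, True)]
        with pytest.raises(ValueError, match="duplicate"):
            build_table([GeneExpression("G", 1, 1.0)], dup)


class TestVenn:
    def test_all_false_records_land_in_none(self):
        records = [rec(f"g{i}", False, False, False, 0.0) for i in range(5)]
        v = venn(records)
        assert v["none"] == v.total == 5

    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_counts_sum_to_total(self, flags):
        records = [rec(f"g{i}", a, b, c, 1.0) for i, (a, b, c) in enumerate(flags)]
        v = venn(records)
        assert sum(v.counts.values()) == len(records) == v.total


class TestOverlapSummary:
    def test_single_group_all_rates_100(self):
        records = [rec(f"g{i}", True, True, True) for i in range(10)]
        df = overlap_summary(venn(records)).set_index("metric")
        for metric in ("rna_coverage_of_ihc", "rna_coverage_of_if",
                       "either_protein_to_both", "all_three"):
            assert df.loc[metric, "percent"] == 100.0

    def test_zero_denominator_is_undefined_not_zero(self):
        records = [rec("g", False, False, False, 0.0)]
        df = overlap_summary(venn(records)).set_index("metric")
        import pandas as pd

        assert pd.isna(df.loc["rna_coverage_of_ihc", "percent"])

    def test_summary_consistent_with_direct_computation(self, fixture_tables):
        """Percentages from Venn counts equal those recomputed from records."""
        expr, calls = fixture_tables
        records = build_table(expr, calls)
        df = overlap_summary(venn(records)).set_index("metric")
        ihc_present = [r for r in records if r.ihc_present]
        direct = 100.0 * sum(r.rna_present for r in ihc_present) / len(ihc_present)
        assert df.loc["rna_coverage_of_ihc", "percent"] == pytest.approx(direct)


class TestAssociation:
    def test_independent_table_gives_zero_statistic(self):
        r = association_test(ContingencyTable2x2([[50, 50], [50, 50]]), correction=False)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_diagonal_table_hand_computed(self):
        # all E = 5 -> sum (O-E)^2/E = 4 * 25/5 = 20
        r = association_test(ContingencyTable2x2([[10, 0], [0, 10]]), correction=False)
        assert r.statistic == pytest.approx(20.0)

    def test_zero_expected_cell_raises(self):
        with pytest.raises(ValueError, match="exact"):
            association_test(ContingencyTable2x2([[0, 0], [5, 5]]))

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_uncorrected_matches_closed_form(self, cells):
        """Pearson chi2 equals N(ad-bc)^2 / (r1 r2 c1 c2)."""
        a, b, c, d = cells
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        r = association_test(ContingencyTable2x2([[a, b], [c, d]]), correction=False)
        assert r.statistic == pytest.approx(closed, rel=1e-9)

    def test_contingency_from_records(self):
        records = [rec("a", True, False, True), rec("b", False, False, True),
                   rec("c", True, False, False), rec("d", False, True, False)]
        t = contingency_rna_protein(records, "ihc")
        assert t.observed.tolist() == [[1, 1], [1, 1]]


class TestCdfs:
    def test_cdf_step_values(self):
        records = [rec(f"g{i}", False, False, True, x) for i, x in enumerate([1, 2, 3])]
        cdfs = expression_cdf_by_group(records, groups=("C",))
        assert cdfs["C"](2.0) == pytest.approx(2 / 3)
        assert cdfs["all"](3.0) == 1.0

    def test_low_tail_group_dominates_reference(self):
        rng = np.random.default_rng(1)
        all_vals = rng.lognormal(1, 1, 400)
        median = np.median(all_vals)
        records = [rec(f"a{i}", True, True, True, float(x)) for i, x in enumerate(all_vals)]
        low = [rec(f"c{i}", False, False, True, float(x))
               for i, x in enumerate(all_vals[all_vals < median])]
        cdfs = expression_cdf_by_group(records + low, groups=("C", "ABC"))
        grid = np.concatenate([c.values for c in cdfs.values()])
        assert (cdfs["C"](grid) >= cdfs["all"](grid) - 1e-12).all()

    def test_empty_group_omitted_with_warning(self, caplog):
        records = [rec("g", True, True, True, 1.0)]
        with caplog.at_level("WARNING"):
            cdfs = expression_cdf_by_group(records, groups=("C",))
        assert "C" not in cdfs and "all" in cdfs


def brute_force_ks(sample, reference, alternative):
    """Max one-sided CDF difference over every pooled evaluation point."""
    pts = sorted(set(sample) | set(reference))
    best = 0.0
    for t in pts:
        fs = sum(x <= t for x in sample) / len(sample)
        fr = sum(x <= t for x in reference) / len(reference)
        diff = fs - fr if alternative == "lower" else fr - fs
        best = max(best, diff)
    return best


class TestKsOneSided:
    def test_identical_samples(self):
        r = ks_one_sided([1, 2, 3], [1, 2, 3], "lower")
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_disjoint_supports(self):
        r = ks_one_sided([1, 2], [3, 4], "lower")
        assert r.statistic == 1.0

    def test_statistic_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            s = rng.lognormal(0, 1, 20)
            ref = rng.lognormal(0.5, 1, 50)
            for alt in ("lower", "greater"):
                r = ks_one_sided(s, ref, alt)
                assert r.statistic == pytest.approx(brute_force_ks(s, ref, alt))
                assert 0.0 <= r.statistic <= 1.0
        # independent cross-check: scipy's one-sided D+ ("greater" on the
        # first sample's CDF) is our "lower" alternative
        from scipy.stats import ks_2samp

        s = rng.lognormal(0, 1, 30)
        ref = rng.lognormal(0.3, 1, 40)
        assert ks_one_sided(s, ref, "lower").statistic == pytest.approx(
            ks_2samp(s, ref, alternative="greater").statistic
        )

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            ks_one_sided([1.0], [1.0, 2.0])


def binned_records(n, rng, monotone=True):
    xs = np.sort(rng.lognormal(1, 1.5, n))[::-1]
    out = []
    for i, x in enumerate(xs):
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * np.log10(x + 0.01)))) if monotone else 0.5
        out.append(rec(f"g{i:05d}", rng.random() < p, rng.random() < p, True, float(x)))
    return out


class TestBinOverlap:
    def test_equal_bin_sizes(self):
        rng = np.random.default_rng(0)
        res = bin_overlap(binned_records(100, rng), n_bins=25)
        assert [b.n_genes for b in res.bins] == [4] * 25
        assert sum(b.n_genes for b in res.bins) == 100

    def test_remainder_spread_over_top_bins(self):
        rng = np.random.default_rng(0)
        res = bin_overlap(binned_records(103, rng), n_bins=25)
        sizes = [b.n_genes for b in res.bins]
        assert sizes[:3] == [5, 5, 5] and set(sizes[3:]) == {4}

    def test_all_present_gives_100_everywhere(self):
        records = [rec(f"g{i}", True, True, True, float(i)) for i in range(50)]
        res = bin_overlap(records, n_bins=10)
        assert all(b.pct_ihc_present == 100.0 for b in res.bins)
        assert res.top_half.pct_if_present == 100.0

    def test_monotone_detection_gives_ordered_halves(self):
        rng = np.random.default_rng(123)
        res = bin_overlap(binned_records(5000, rng), n_bins=25)
        assert res.top_half.pct_ihc_present >= res.bottom_half.pct_ihc_present
        assert res.top_half.pct_if_present >= res.bottom_half.pct_if_present

    def test_weighted_bin_mean_equals_overall_rate(self):
        rng = np.random.default_rng(7)
        records = binned_records(997, rng)
        res = bin_overlap(records, n_bins=25)
        weighted = sum(b.pct_ihc_present * b.n_genes for b in res.bins) / len(records)
        overall = 100.0 * sum(r.ihc_present for r in records) / len(records)
        assert weighted == pytest.approx(overall)

    def test_supportive_wb_restriction_filters_denominator(self):
        from xconcord.models import ValidationCategory as VC

        records = [
            rec(f"g{i}", True, True, True, float(i),
                wb_category=VC.supportive if i % 2 else VC.uncertain)
            for i in range(40)
        ]
        res = bin_overlap(records, n_bins=2, restrict_supportive_wb=True)
        assert sum(b.n_genes for b in res.bins) == 20

    def test_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            bin_overlap(binned_records(10, rng), n_bins=25)
        with pytest.raises(ValueError):
            bin_overlap(binned_records(10, rng), n_bins=1)
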