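"""Clear-zone uniqueness, exon-containment assignment, counting and RPKM."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from xconcord.models import GeneModel, GenomicInterval, ReadAlignment, ReadHit
from xconcord.read_quant import (
    GeneIndex,
    QuantConfig,
    assign_read_to_genes,
    classify_read,
    presence_rate,
    quantify,
)


def aln(mismatches, read_id="r", length=35):
    """Build a read whose hits differ only in mismatch count."""
    hits = [
        ReadHit(GenomicInterval(f"chr{i}", 1000 * i, 1000 * i + length), m)
        for i, m in enumerate(mismatches)
    ]
    return ReadAlignment(read_id, length, hits)


def brute_force_status(mismatches, max_mm, z):
    """Independent enumeration of the uniqueness rule over a mismatch list."""
    if not mismatches:
        return "unmapped"
    n_star = min(mismatches)
    if n_star > max_mm:
        return "discarded_mismatch"
    best_hits = [m for m in mismatches if m == n_star]
    zone_hits = [m for m in mismatches if n_star + 1 <= m <= n_star + z]
    if len(best_hits) == 1 and not zone_hits:
        return "unique"
    return "ambiguous"


class TestClassifyRead:
    @pytest.mark.parametrize(
        "mms, expected",
        [
            ([0], "unique"),                 # single perfect hit
            ([1, 2], "ambiguous"),           # second hit inside the clear zone
            ([0, 3], "unique"),              # 3 > 0+2: outside the zone
            ([4], "discarded_mismatch"),     # best hit above the cap
            ([], "unmapped"),
            ([1, 1], "ambiguous"),           # tie at the minimum
            ([0, 2, 5], "ambiguous"),
            ([3, 6], "unique"),              # best exactly at the cap
        ],
    )
    def test_rule_examples(self, mms, expected):
        dec = classify_read(aln(mms), QuantConfig())
        assert dec.status == expected
        if expected == "unique":
            assert dec.chosen_hit.mismatches_n == min(mms)
        else:
            assert dec.chosen_hit is None

    def test_exhaustive_agreement_with_brute_force(self):
        """Rule matches enumeration for every hit list of length <= 4, mm 0..5."""
        cfg = QuantConfig()
        for k in range(0, 5):
            for mms in itertools.product(range(6), repeat=k):
                dec = classify_read(aln(list(mms)), cfg)
                assert dec.status == brute_force_status(list(mms), 3, 2), mms

    @given(
        st.lists(st.integers(0, 8), max_size=6),
        st.integers(0, 5),
        st.integers(0, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_agreement_for_arbitrary_config(self, mms, max_mm, z):
        cfg = QuantConfig(max_mismatches=max_mm, clear_zone_z=z)
        assert classify_read(aln(mms), cfg).status == brute_force_status(mms, max_mm, z)


GENES = [
    GeneModel("G1", [GenomicInterval("c", 100, 200), GenomicInterval("c", 400, 500)]),
    GeneModel("G2", [GenomicInterval("c", 150, 260)]),  # overlaps G1's first exon
    GeneModel("G3", [GenomicInterval("c", 1000, 1400)]),
]


def hit(start, end, chrom="c"):
    return ReadHit(GenomicInterval(chrom, start, end), 0)


class TestAssignment:
    def test_contained_hit_assigns_to_gene(self):
        assert assign_read_to_genes(hit(110, 145), GENES) == ["G1"]

    def test_straddling_hit_is_excluded(self):
        # 35 bp spanning G1's exon end at 200: partial overlap does not count
        assert assign_read_to_genes(hit(195, 230), [GENES[0], GENES[2]]) == []

    def test_hit_in_two_overlapping_genes_assigns_to_both(self):
        got = assign_read_to_genes(hit(160, 195), GENES)
        # brute-force scan over both gene models
        expected = sorted(
            g.gene_id
            for g in GENES
            if any(iv.contains(GenomicInterval("c", 160, 195)) for iv in g.exons)
        )
        assert sorted(got) == expected == ["G1", "G2"]

    def test_intergenic_hit_assigns_nowhere(self):
        assert assign_read_to_genes(hit(700, 735), GENES) == []

    def test_merged_mode_allows_containment_across_joined_exons(self):
        g = GeneModel("J", [GenomicInterval("c", 100, 200), GenomicInterval("c", 200, 300)])
        idx_single = GeneIndex([g], "single_exon")
        idx_merged = GeneIndex([g], "merged_exons")
        spanning = hit(180, 215)
        assert idx_single.containing_genes(spanning) == []
        assert idx_merged.containing_genes(spanning) == ["J"]


class TestQuantify:
    def test_hand_placed_reads_toy_model(self):
        """3-gene toy set with hand-placed reads -> counts (2, 0, 5), N = 7."""
        reads = (
            [ReadAlignment(f"a{i}", 35, [hit(100 + i, 135 + i)]) for i in range(2)]
            + [ReadAlignment(f"c{i}", 35, [hit(1000 + 5 * i, 1035 + 5 * i)]) for i in range(5)]
        )
        genes = [GENES[0], GeneModel("G0", [GenomicInterval("q", 0, 100)]), GENES[2]]
        res = quantify(reads, genes)
        by_gene = {e.gene_id: e for e in res.expression}
        assert by_gene["G1"].unique_exonic_reads_C == 2
        assert by_gene["G0"].unique_exonic_reads_C == 0
        assert by_gene["G3"].unique_exonic_reads_C == 5
        assert res.library_size_N == 7
        assert not by_gene["G0"].rna_present and by_gene["G1"].rna_present

    def test_rpkm_closed_form(self):
        """C=10, L=1000, N=1e6 -> RPKM 10."""
        genes = [GeneModel("G", [GenomicInterval("c", 0, 1000)])]
        reads = [ReadAlignment(f"r{i}", 35, [hit(i, 35 + i)]) for i in range(10)]
        res = quantify(reads, genes, QuantConfig(library_size_N=10**6))
        assert res.expression[0].rpkm == pytest.approx(10.0)

    def test_rpkm_scale_invariance(self):
        """Duplicating every read and doubling N leaves RPKM unchanged."""
        genes = [GeneModel("G", [GenomicInterval("c", 0, 1000)])]
        reads = [ReadAlignment(f"r{i}", 35, [hit(3 * i, 35 + 3 * i)]) for i in range(20)]
        res1 = quantify(reads, genes, QuantConfig(library_size_N=1000))
        doubled = reads + [
            ReadAlignment(a.read_id + "_dup", a.read_length, a.hits) for a in reads
        ]
        res2 = quantify(doubled, genes, QuantConfig(library_size_N=2000))
        assert res1.expression[0].rpkm == pytest.approx(res2.expression[0].rpkm)

    def test_count_conservation_without_gene_overlap(self, small_dataset):
        """Sum of per-gene counts equals assigned reads on an overlap-free model."""
        res = quantify(small_dataset.alignments, small_dataset.genes)
        assert sum(e.unique_exonic_reads_C for e in res.expression) == res.n_assigned

    def test_overlapping_genes_can_exceed_assigned(self):
        reads = [ReadAlignment("r", 35, [hit(160, 195)])]
        res = quantify(reads, GENES, QuantConfig(library_size_N=1))
        assert sum(e.unique_exonic_reads_C for e in res.expression) == 2
        assert res.n_assigned == 1

    def test_discard_shared_policy(self):
        reads = [ReadAlignment("r", 35, [hit(160, 195)])]
        res = quantify(reads, GENES, QuantConfig(library_size_N=1),
                       multi_gene="discard_shared")
        assert sum(e.unique_exonic_reads_C for e in res.expression) == 0

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty library"):
            quantify([], GENES)

    def test_rank_correlation_with_truth(self, small_dataset):
        """Measured RPKM tracks true abundance on simulated data."""
        from scipy.stats import spearmanr

        res = quantify(small_dataset.alignments, small_dataset.genes)
        measured = {e.gene_id: e.rpkm for e in res.expression}
        tr = small_dataset.truth
        deep = tr[tr.reads_simulated >= 50]
        rho = spearmanr(
            deep.true_rpkm, [measured[g] for g in deep.gene_id]
        ).statistic
        assert rho > 0.9


class TestPresenceRate:
    def test_published_scale_example(self):
        from xconcord.models import GeneExpression

        expr = [GeneExpression(f"g{i}", 1, 1.0) for i in range(15536)]
        expr += [GeneExpression(f"z{i}", 0, 0.0) for i in range(21146 - 15536)]
        pr = presence_rate(expr)
        assert pr.n_present == 15536 and pr.n_total == 21146
        assert pr.percent == pytest.approx(73.47, abs=1e-2)

    def test_edge_rates(self):
        from xconcord.models import GeneExpression

        assert presence_rate([GeneExpression("a", 2, 1.0)]).percent == 100.0
        mixed = [GeneExpression("a", 1, 1.0), GeneExpression("b", 0, 0.0),
                 GeneExpression("c", 0, 0.0)]
        assert presence_rate(mixed).percent == pytest.approx(33.333, abs=1e-2)
        with pytest.raises(ValueError):
            presence_rate([])
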