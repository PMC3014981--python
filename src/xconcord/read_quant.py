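"""Read-level quantification: clear-zone uniqueness, exon containment, RPKM.

A read is *unique* when exactly one of its candidate hits achieves the
minimal mismatch count N* and no other hit falls within the clear zone
[N*+1, N*+z]; reads whose best hit exceeds the mismatch cap are discarded.
Unique reads are assigned to every gene with an exon (or merged-exon block)
that fully contains the hit span.  Per-gene expression is summarised as

    RPKM_g = 1e9 * C_g / (L_g * N)

with C_g the unique exonic read count, L_g the merged exonic length, and N
the library size (by default the total number of assigned unique exonic
reads).  A gene is called RNA-present when C_g >= 1.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .models import GeneExpression, GeneModel, ReadAlignment, ReadHit

ContainmentMode = Literal["single_exon", "merged_exons"]
MultiGenePolicy = Literal["count_all", "discard_shared"]


@dataclass
class QuantConfig:
    """Uniqueness-filter and RPKM-denominator settings.

    max_mismatches: best-hit mismatch cap (reads above it are discarded).
    clear_zone_z: width of the uniqueness margin in extra mismatches.
    library_size_N: RPKM denominator; None means "total assigned reads".
    """

    max_mismatches: int = 3
    clear_zone_z: int = 2
    library_size_N: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.clear_zone_z < 0:
            raise ValueError("max_mismatches and clear_zone_z must be >= 0")


@dataclass
class UniquenessDecision:
    read_id: str
    status: Literal["unique", "ambiguous", "discarded_mismatch", "unmapped"]
    chosen_hit: Optional[ReadHit] = None

    def __post_init__(self) -> None:
        if (self.chosen_hit is not None) != (self.status == "unique"):
            raise ValueError("chosen_hit must be set iff status is unique")


def classify_read(aln: ReadAlignment, cfg: QuantConfig) -> UniquenessDecision:
    """Apply the clear-zone uniqueness rule to one read's hit list."""
    if not aln.hits:
        return UniquenessDecision(aln.read_id, "unmapped")
    mms = [h.mismatches_n for h in aln.hits]
    n_star = min(mms)
    if n_star > cfg.max_mismatches:
        return UniquenessDecision(aln.read_id, "discarded_mismatch")
    if mms.count(n_star) != 1:
        return UniquenessDecision(aln.read_id, "ambiguous")
    if any(n_star + 1 <= m <= n_star + cfg.clear_zone_z for m in mms):
        return UniquenessDecision(aln.read_id, "ambiguous")
    best = aln.hits[mms.index(n_star)]
    return UniquenessDecision(aln.read_id, "unique", chosen_hit=best)


class GeneIndex:
    """Per-chromosome sorted exon intervals for containment queries.

    Intervals are the individual exons (single_exon mode) or the merged-exon
    blocks (merged_exons mode, allowing containment across exon joins).
    """

    def __init__(self, genes: Iterable[GeneModel], mode: ContainmentMode = "single_exon"):
        if mode not in ("single_exon", "merged_exons"):
            raise ValueError(f"unknown containment mode {mode!r}")
        self.mode = mode
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for g in genes:
            ivs = g.exons if mode == "single_exon" else g.merged_exons
            for iv in ivs:
                self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, g.gene_id))
        for chrom, ivs in self._by_chrom.items():
            ivs.sort()
            self._starts[chrom] = [s for s, _, _ in ivs]
            self._max_len[chrom] = max(e - s for s, e, _ in ivs)

    def containing_genes(self, hit: ReadHit) -> list[str]:
        """Gene ids with an interval fully containing the hit span (deduplicated)."""
        chrom = hit.location.chrom
        if chrom not in self._by_chrom:
            return []
        ivs = self._by_chrom[chrom]
        starts = self._starts[chrom]
        # candidate intervals start in (hit.start - max_len, hit.start]
        lo = bisect.bisect_left(starts, hit.location.start - self._max_len[chrom] + 1)
        hi = bisect.bisect_right(starts, hit.location.start)
        found: list[str] = []
        seen: set[str] = set()
        for s, e, gid in ivs[lo:hi]:
            if e >= hit.location.end and gid not in seen:
                seen.add(gid)
                found.append(gid)
        return found


def assign_read_to_genes(
    hit: ReadHit,
    genes: GeneIndex | Iterable[GeneModel],
    containment_mode: ContainmentMode = "single_exon",
) -> list[str]:
    """Genes whose exon (or merged block) fully contains the unique hit."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, containment_mode)
    return index.containing_genes(hit)


@dataclass
class QuantResult:
    """Per-gene expression plus bookkeeping from the uniqueness filter."""

    expression: list[GeneExpression]
    library_size_N: int
    n_reads: int = 0
    n_unique: int = 0
    n_ambiguous: int = 0
    n_discarded_mismatch: int = 0
    n_unmapped: int = 0
    n_assigned: int = 0  # unique reads contained in >= 1 gene

    @property
    def ambiguous_fraction(self) -> float:
        return self.n_ambiguous / self.n_reads if self.n_reads else 0.0


def quantify(
    alignments: Iterable[ReadAlignment],
    genes: list[GeneModel],
    cfg: Optional[QuantConfig] = None,
    containment_mode: ContainmentMode = "single_exon",
    multi_gene: MultiGenePolicy = "count_all",
) -> QuantResult:
    """Count unique exonic reads per gene and compute RPKM.

    Reads contained in exons of several overlapping genes count for each of
    them under ``count_all`` (the default) or for none under
    ``discard_shared``; either way the read contributes once to the
    default library size.
    """
    cfg = cfg or QuantConfig()
    index = GeneIndex(genes, containment_mode)
    counts: dict[str, int] = {g.gene_id: 0 for g in genes}
    res = QuantResult(expression=[], library_size_N=0)
    for aln in alignments:
        res.n_reads += 1
        dec = classify_read(aln, cfg)
        if dec.status == "unique":
            res.n_unique += 1
            gene_ids = index.containing_genes(dec.chosen_hit)
            if gene_ids:
                res.n_assigned += 1
                if multi_gene == "count_all" or len(gene_ids) == 1:
                    for gid in gene_ids:
                        counts[gid] += 1
        elif dec.status == "ambiguous":
            res.n_ambiguous += 1
        elif dec.status == "discarded_mismatch":
            res.n_discarded_mismatch += 1
        else:
            res.n_unmapped += 1
    N = cfg.library_size_N if cfg.library_size_N is not None else res.n_assigned
    if N <= 0:
        raise ValueError("empty library: RPKM denominator N is zero")
    res.library_size_N = N
    for g in genes:
        c = counts[g.gene_id]
        rpkm = 1e9 * c / (g.exonic_length_L * N)
        res.expression.append(GeneExpression(g.gene_id, c, rpkm))
    return res


@dataclass
class PresenceRate:
    n_present: int
    n_total: int
    fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.fraction = self.n_present / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    def __str__(self) -> str:
        return f"{self.percent:.1f}% ({self.n_present}/{self.n_total})"


def presence_rate(expr: list[GeneExpression]) -> PresenceRate:
    """Fraction of genes with at least one uniquely mapped exonic read."""
    if not expr:
        raise ValueError("presence_rate of empty expression list")
    return PresenceRate(sum(e.rna_present for e in expr), len(expr))
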