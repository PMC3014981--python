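"""Shared domain types for the transcript-protein concordance pipeline.

Coordinates are 0-based, half-open throughout; GTF input (1-based,
inclusive) is converted on read and back on write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

IHC_GRADES = ("negative", "weak", "moderate", "strong")
VENN_GROUPS = ("A", "B", "C", "AB", "AC", "BC", "ABC", "none")

IF_SCORE_MIN, IF_SCORE_MAX = 1, 9
WB_SCORE_MIN, WB_SCORE_MAX = 1, 7
IF_ABSENT_SCORE = 7  # no staining


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a reference chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if `other` lies entirely inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, pairwise-disjoint blocks per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # touching intervals merge too
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass
class GeneModel:
    """A gene as a set of exons; the merged-exon union defines its length L."""

    gene_id: str
    exons: list[GenomicInterval]
    merged_exons: list[GenomicInterval] = field(default_factory=list)
    exonic_length_L: int = 0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if not self.merged_exons:
            self.merged_exons = merge_intervals(self.exons)
            self.exonic_length_L = sum(iv.length for iv in self.merged_exons)
        if self.exonic_length_L <= 0:
            raise ValueError(f"gene {self.gene_id} has non-positive exonic length")


@dataclass(frozen=True)
class ReadHit:
    """One candidate placement of a read, with its mismatch count."""

    location: GenomicInterval
    mismatches_n: int

    def __post_init__(self) -> None:
        if self.mismatches_n < 0:
            raise ValueError("negative mismatch count")


@dataclass
class ReadAlignment:
    """All candidate hits for one read; empty hit list means unmapped."""

    read_id: str
    read_length: int
    hits: list[ReadHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.location.length != self.read_length:
                raise ValueError(
                    f"read {self.read_id}: hit span {h.location.length} "
                    f"!= read length {self.read_length}"
                )


def _check_range(name: str, value: Optional[int], lo: int, hi: int) -> None:
    if value is not None and not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass
class AntibodyRecord:
    """One antibody's IHC/IF/WB annotation for its target gene.

    Missing annotations are None (an empty cell on disk), never 0.
    """

    antibody_id: str
    gene_id: str
    ihc_intensity: Optional[str] = None
    if_score: Optional[int] = None
    wb_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ihc_intensity is not None and self.ihc_intensity not in IHC_GRADES:
            raise ValueError(f"unknown IHC intensity {self.ihc_intensity!r}")
        _check_range("if_score", self.if_score, IF_SCORE_MIN, IF_SCORE_MAX)
        _check_range("wb_score", self.wb_score, WB_SCORE_MIN, WB_SCORE_MAX)


@dataclass
class GeneExpression:
    """Unique-read count C, RPKM, and the derived RNA presence flag."""

    gene_id: str
    unique_exonic_reads_C: int
    rpkm: float
    rna_present: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.unique_exonic_reads_C < 0 or self.rpkm < 0:
            raise ValueError("negative count or RPKM")
        self.rna_present = self.unique_exonic_reads_C >= 1


class ValidationCategory(str, Enum):
    supportive = "supportive"
    uncertain = "uncertain"
    non_supportive = "non_supportive"


@dataclass
class ProteinCalls:
    """Presence calls and validation categories for one gene's selected antibody."""

    gene_id: str
    antibody_id: str
    ihc_present: bool
    if_present: bool
    wb_category: Optional[ValidationCategory] = None
    if_category: Optional[ValidationCategory] = None
    wb_score: Optional[int] = None
    if_score: Optional[int] = None


@dataclass
class ConcordanceRecord:
    """Per-gene presence on the three platforms (A = IHC, B = IF, C = RNA-seq)."""

    gene_id: str
    ihc_present: bool
    if_present: bool
    rna_present: bool
    rpkm: float
    wb_category: Optional[ValidationCategory] = None
    if_category: Optional[ValidationCategory] = None
    wb_score: Optional[int] = None
    if_score: Optional[int] = None

    @property
    def venn_group(self) -> str:
        label = (
            ("A" if self.ihc_present else "")
            + ("B" if self.if_present else "")
            + ("C" if self.rna_present else "")
        )
        return label or "none"


@dataclass
class VennCounts:
    """Counts of the eight presence patterns over three platforms."""

    counts: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        for g in VENN_GROUPS:
            self.counts.setdefault(g, 0)
        unknown = set(self.counts) - set(VENN_GROUPS)
        if unknown:
            raise ValueError(f"unknown venn groups: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative venn count")
        self.total = sum(self.counts.values())

    def __getitem__(self, group: str) -> int:
        return self.counts[group]

    def marginal(self, platform: str) -> int:
        """Genes present on one platform, any combination: 'A', 'B' or 'C'."""
        if platform not in ("A", "B", "C"):
            raise ValueError(f"platform must be A, B or C, got {platform!r}")
        return sum(c for g, c in self.counts.items() if platform in g)


@dataclass
class TestResult:
    """A statistic with its p-value and enough metadata to reproduce it."""

    method: str
    statistic: float
    p_value: float
    sidedness: str = "two_sided"
    df: Optional[int] = None
    replicates: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
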