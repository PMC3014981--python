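"""Readers and writers for gene models, alignments, and antibody tables.

Supported formats: GTF (Ensembl dialect, exon features) and BED12 for gene
models; SAM/BAM with NM tags or a plain multi-hit TSV for alignments; TSV
for antibody annotations and all pipeline outputs.  All tabular outputs are
tab-separated with a header line.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
import pysam

from .models import (
    AntibodyRecord,
    GeneExpression,
    GeneModel,
    GenomicInterval,
    ProteinCalls,
    ReadAlignment,
    ReadHit,
    ValidationCategory,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_GTF_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


class ParseError(ValueError):
    """A malformed record, reported with its file line number."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene models from GTF or BED12, sniffing the format.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention; BED is already native.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    # sniff: BED12 rows have 12 columns with integer column 7
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 12 and fields[6].isdigit():
                return _read_bed12(path)
            return _read_gtf(path)
    return []


def _read_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, list[GenomicInterval]] = {}
    declared_genes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature == "gene":
                m = _GTF_GENE_ID_RE.search(attrs)
                if m:
                    declared_genes.append(m.group(1))
                continue
            if feature != "exon":
                continue
            m = _GTF_GENE_ID_RE.search(attrs)
            if m is None:
                raise ParseError(f"{path}:{lineno}: exon without gene_id attribute")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}:{lineno}: bad GTF coordinates {start}..{end}")
            # GTF is 1-based inclusive -> 0-based half-open
            exons.setdefault(m.group(1), []).append(
                GenomicInterval(chrom, start_i - 1, end_i, strand if strand in "+-" else ".")
            )
    for gid in declared_genes:
        if gid not in exons:
            log.warning("gene %s declared but has zero exons; rejected", gid)
    return [GeneModel(gene_id=gid, exons=ivs) for gid, ivs in exons.items()]


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            try:
                chrom, chrom_start = f[0], int(f[1])
                name, strand = f[3], f[5]
                block_sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 fields") from exc
            if len(block_sizes) != len(block_starts):
                raise ParseError(f"{path}:{lineno}: blockSizes/blockStarts length mismatch")
            exons = [
                GenomicInterval(
                    chrom,
                    chrom_start + bs,
                    chrom_start + bs + sz,
                    strand if strand in "+-" else ".",
                )
                for sz, bs in zip(block_sizes, block_starts)
            ]
            genes.append(GeneModel(gene_id=name, exons=exons))
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write exon features as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            for iv in g.exons:
                fh.write(
                    f"{iv.chrom}\txconcord\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand if iv.strand in '+-' else '.'}\t.\t"
                    f'gene_id "{g.gene_id}";\n'
                )


# ---------------------------------------------------------------------------
# read alignments
# ---------------------------------------------------------------------------

ALIGNMENT_TSV_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "mismatches"]


def read_alignments(path: PathLike) -> Iterator[ReadAlignment]:
    """Stream multi-hit read alignments from SAM/BAM (NM tags) or TSV.

    Hits are grouped by read id; the order of first appearance is preserved
    and hit order within a read follows the input.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        yield from _read_alignments_sam(path)
    else:
        yield from _read_alignments_tsv(path)


def _read_alignments_sam(path: Path) -> Iterator[ReadAlignment]:
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    grouped: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            name = rec.query_name
            if name not in grouped:
                length = rec.query_length or (rec.infer_read_length() or 0)
                grouped[name] = ReadAlignment(read_id=name, read_length=length, hits=[])
            aln = grouped[name]
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NM"):
                raise ParseError(f"{path}: read {name}: mapped record lacks NM tag")
            if aln.read_length == 0:
                aln.read_length = rec.reference_end - rec.reference_start
            loc = GenomicInterval(
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + aln.read_length,
                "-" if rec.is_reverse else "+",
            )
            aln.hits.append(ReadHit(location=loc, mismatches_n=int(rec.get_tag("NM"))))
    yield from grouped.values()


def _read_alignments_tsv(path: Path) -> Iterator[ReadAlignment]:
    grouped: dict[str, ReadAlignment] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ALIGNMENT_TSV_COLUMNS:
            raise ParseError(
                f"{path}: expected header {ALIGNMENT_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            read_id, chrom, start, end, strand, mm = f
            if mm == "":
                raise ParseError(f"{path}:{lineno}: read {read_id}: missing mismatch count")
            try:
                start_i, end_i, mm_i = int(start), int(end), int(mm)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if start_i < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            if chrom == "*":  # unmapped placeholder row
                grouped.setdefault(
                    read_id, ReadAlignment(read_id=read_id, read_length=end_i - start_i)
                )
                continue
            length = end_i - start_i
            aln = grouped.setdefault(
                read_id, ReadAlignment(read_id=read_id, read_length=length)
            )
            aln.hits.append(
                ReadHit(
                    location=GenomicInterval(chrom, start_i, end_i, strand),
                    mismatches_n=mm_i,
                )
            )
    yield from grouped.values()


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_TSV_COLUMNS) + "\n")
        for aln in alignments:
            if not aln.hits:
                fh.write(f"{aln.read_id}\t*\t0\t{aln.read_length}\t.\t0\n")
                continue
            for h in aln.hits:
                iv = h.location
                fh.write(
                    f"{aln.read_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{h.mismatches_n}\n"
                )


# ---------------------------------------------------------------------------
# antibody tables and pipeline tables
# ---------------------------------------------------------------------------

ANTIBODY_COLUMNS = ["antibody_id", "gene_id", "ihc_intensity", "if_score", "wb_score"]


def read_antibody_table(path: PathLike) -> list[AntibodyRecord]:
    """Read antibody annotations; empty cells mean missing, scores are range-checked."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANTIBODY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                AntibodyRecord(
                    antibody_id=row.antibody_id,
                    gene_id=row.gene_id,
                    ihc_intensity=row.ihc_intensity or None,
                    if_score=int(row.if_score) if row.if_score != "" else None,
                    wb_score=int(row.wb_score) if row.wb_score != "" else None,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_no}: {exc}") from exc
    return records


def write_antibody_table(records: Iterable[AntibodyRecord], path: PathLike) -> None:
    rows = [
        {
            "antibody_id": r.antibody_id,
            "gene_id": r.gene_id,
            "ihc_intensity": r.ihc_intensity or "",
            "if_score": "" if r.if_score is None else r.if_score,
            "wb_score": "" if r.wb_score is None else r.wb_score,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANTIBODY_COLUMNS).to_csv(path, sep="\t", index=False)


def write_expression_table(expr: Iterable[GeneExpression], path: PathLike) -> None:
    rows = [
        {
            "gene_id": e.gene_id,
            "reads": e.unique_exonic_reads_C,
            "rpkm": f"{e.rpkm:.6g}",
            "present": int(e.rna_present),
        }
        for e in expr
    ]
    pd.DataFrame(rows, columns=["gene_id", "reads", "rpkm", "present"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_table(path: PathLike) -> list[GeneExpression]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneExpression(
            gene_id=str(r.gene_id),
            unique_exonic_reads_C=int(r.reads),
            rpkm=float(r.rpkm),
        )
        for r in df.itertuples(index=False)
    ]


CALLS_COLUMNS = [
    "gene_id", "antibody_id", "ihc_present", "if_present",
    "wb_category", "if_category", "wb_score", "if_score",
]


def write_calls_table(calls: Iterable[ProteinCalls], path: PathLike) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "antibody_id": c.antibody_id,
            "ihc_present": int(c.ihc_present),
            "if_present": int(c.if_present),
            "wb_category": c.wb_category.value if c.wb_category else "",
            "if_category": c.if_category.value if c.if_category else "",
            "wb_score": "" if c.wb_score is None else c.wb_score,
            "if_score": "" if c.if_score is None else c.if_score,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALLS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_table(path: PathLike) -> list[ProteinCalls]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for r in df.itertuples(index=False):
        calls.append(
            ProteinCalls(
                gene_id=r.gene_id,
                antibody_id=r.antibody_id,
                ihc_present=bool(int(r.ihc_present)),
                if_present=bool(int(r.if_present)),
                wb_category=ValidationCategory(r.wb_category) if r.wb_category else None,
                if_category=ValidationCategory(r.if_category) if r.if_category else None,
                wb_score=int(r.wb_score) if r.wb_score != "" else None,
                if_score=int(r.if_score) if r.if_score != "" else None,
            )
        )
    return calls
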