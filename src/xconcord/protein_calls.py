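"""Antibody-based protein presence calls and the non-redundant gene subset.

IHC staining intensity (negative/weak/moderate/strong) gives a presence
call: absent iff negative.  The IF validation score (nine grades) gives a
presence call: absent iff score 7, the "no staining" grade.  Western-blot
validation scores (seven grades) map onto three reliability categories:
1-3 supportive, 4-5 uncertain, 6-7 non-supportive.

The non-redundant subset keeps, for every gene with at least one antibody
annotated on *both* IHC and IF, the best-scoring (lowest) IF antibody, so
each surviving gene carries exactly one antibody's calls.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .models import (
    IF_ABSENT_SCORE,
    AntibodyRecord,
    ProteinCalls,
    ValidationCategory,
)

#: Western-blot score -> reliability category.
WB_CATEGORY_MAP: dict[int, ValidationCategory] = {
    1: ValidationCategory.supportive,
    2: ValidationCategory.supportive,
    3: ValidationCategory.supportive,
    4: ValidationCategory.uncertain,
    5: ValidationCategory.uncertain,
    6: ValidationCategory.non_supportive,
    7: ValidationCategory.non_supportive,
}

#: IF validation score -> reliability category.  Grade 7 means "no staining"
#: (absence), so it carries no category.  The exact published grouping of the
#: nine grades is not restated here; this default (1-3 supportive, 4-6
#: uncertain, 8-9 non-supportive) is configurable wherever it is consumed.
IF_CATEGORY_MAP: dict[int, Optional[ValidationCategory]] = {
    1: ValidationCategory.supportive,
    2: ValidationCategory.supportive,
    3: ValidationCategory.supportive,
    4: ValidationCategory.uncertain,
    5: ValidationCategory.uncertain,
    6: ValidationCategory.uncertain,
    7: None,
    8: ValidationCategory.non_supportive,
    9: ValidationCategory.non_supportive,
}


def call_ihc(intensity: Optional[str]) -> bool:
    """Protein present iff staining intensity is weak, moderate or strong."""
    if intensity is None:
        raise ValueError("missing IHC intensity; exclude the gene upstream")
    if intensity not in ("negative", "weak", "moderate", "strong"):
        raise ValueError(f"unknown IHC intensity {intensity!r}")
    return intensity != "negative"


def call_if(if_score: Optional[int]) -> bool:
    """Protein present iff the IF validation score is not 7 (no staining)."""
    if if_score is None:
        raise ValueError("missing IF score; exclude the gene upstream")
    if not 1 <= if_score <= 9:
        raise ValueError(f"IF score {if_score} outside 1..9")
    return if_score != IF_ABSENT_SCORE


def wb_category(wb_score: Optional[int],
                category_map: Mapping[int, ValidationCategory] = WB_CATEGORY_MAP,
                ) -> Optional[ValidationCategory]:
    if wb_score is None:
        return None
    return category_map[wb_score]


def if_category(if_score: Optional[int],
                category_map: Mapping[int, Optional[ValidationCategory]] = IF_CATEGORY_MAP,
                ) -> Optional[ValidationCategory]:
    if if_score is None:
        return None
    return category_map[if_score]


def _is_dual_platform(r: AntibodyRecord) -> bool:
    return r.ihc_intensity is not None and r.if_score is not None


def select_antibody(candidates: Sequence[AntibodyRecord]) -> AntibodyRecord:
    """Pick the best-scoring IF antibody for a gene.

    Lower IF score is better; ties break on lowest WB score (missing worst),
    then on antibody id for full determinism.
    """
    if not candidates:
        raise ValueError("select_antibody on empty candidate list")
    for r in candidates:
        if not _is_dual_platform(r):
            raise ValueError(
                f"antibody {r.antibody_id} lacks IHC or IF data; filter first"
            )
    return min(
        candidates,
        key=lambda r: (r.if_score, r.wb_score if r.wb_score is not None else 8, r.antibody_id),
    )


def build_hpa_subset(
    all_records: Sequence[AntibodyRecord],
    if_category_map: Mapping[int, Optional[ValidationCategory]] = IF_CATEGORY_MAP,
    wb_category_map: Mapping[int, ValidationCategory] = WB_CATEGORY_MAP,
) -> list[ProteinCalls]:
    """One ProteinCalls per gene having >= 1 antibody with both IHC and IF data.

    The selected antibody carries all of the gene's calls; its WB category
    stays missing if that antibody has no WB score (no fallback to another
    antibody).  Output is sorted by gene id and gene ids are unique.
    """
    by_gene: dict[str, list[AntibodyRecord]] = {}
    for r in all_records:
        if _is_dual_platform(r):
            by_gene.setdefault(r.gene_id, []).append(r)
    calls: list[ProteinCalls] = []
    for gene_id in sorted(by_gene):
        ab = select_antibody(by_gene[gene_id])
        calls.append(
            ProteinCalls(
                gene_id=gene_id,
                antibody_id=ab.antibody_id,
                ihc_present=call_ihc(ab.ihc_intensity),
                if_present=call_if(ab.if_score),
                wb_category=wb_category(ab.wb_score, wb_category_map),
                if_category=if_category(ab.if_score, if_category_map),
                wb_score=ab.wb_score,
                if_score=ab.if_score,
            )
        )
    return calls
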