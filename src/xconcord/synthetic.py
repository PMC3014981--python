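"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators live here:

* :func:`simulate` draws a full dataset — gene models, short multi-hit read
  alignments with mismatch counts, and an antibody panel — from an explicit
  generative model: zero-inflated log-normal expression, reads placed
  uniformly inside exons, decoy hits on a separate decoy chromosome so
  ground truth stays unambiguous, logistic protein detection that rises
  with expression, and antibody false positives that rise as validation
  quality falls.

* :func:`published_counts_fixture` deterministically builds the 2749-gene three-platform
  presence table whose eight-way Venn partition matches the published study
  counts exactly, with RPKM values drawn so that the RNA-only and IF+RNA
  groups sit in the low-expression tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    AntibodyRecord,
    GeneExpression,
    GeneModel,
    GenomicInterval,
    ProteinCalls,
    ReadAlignment,
    ReadHit,
)
from .protein_calls import if_category, wb_category

DECOY_CHROM = "chrDecoy"


@dataclass
class SimulationConfig:
    """Generative-model settings; every distributional choice lives here.

    Expression is a zero-inflated log-normal: a fraction ``pi_zero`` of
    genes is silent (the study observed ~26.6% of genes without a single
    uniquely mapped read), the rest draw log-normal abundances.  Protein
    detection follows P(present) = logistic(alpha + beta * log10(rpkm + eps))
    per platform, with IF given the steeper slope (it tracks transcription
    more closely at the low end) and IHC the higher intercept (it calls more
    genes present overall).  Antibody false positives depend on a latent
    quality band; poor-quality antibodies both score badly and stain
    unspecifically.
    """

    n_genes: int = 1000
    exon_count_min: int = 1
    exon_count_max: int = 8
    exon_length_min: int = 150
    exon_length_max: int = 600
    intron_length: int = 100
    intergenic_gap: int = 500

    pi_zero: float = 0.266
    log_mu: float = 1.0
    log_sigma: float = 1.2

    depth: int = 100_000
    read_length: int = 35
    multimap_rate: float = 0.2
    clear_zone_violation_rate: float = 0.5
    clear_zone_z: int = 2
    mismatch_probs: tuple[float, ...] = (0.55, 0.25, 0.12, 0.08)  # over 0..3

    alpha_ihc: float = 1.5
    beta_ihc: float = 0.8
    alpha_if: float = 0.2
    beta_if: float = 1.0
    rpkm_epsilon: float = 0.01

    quality_probs: tuple[float, float, float] = (0.60, 0.25, 0.15)  # good/medium/poor
    fp_rates: tuple[float, float, float] = (0.02, 0.10, 0.35)
    wb_missing_rate: float = 0.10
    p_second_antibody: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.exon_length_min:
            raise ValueError(
                f"read_length {self.read_length} exceeds shortest exon "
                f"{self.exon_length_min}; reads could not fall inside an exon"
            )
        for p in (self.pi_zero, self.multimap_rate, self.clear_zone_violation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.mismatch_probs) - 1.0) > 1e-9:
            raise ValueError("mismatch_probs must sum to 1")
        if self.beta_ihc < 0 or self.beta_if < 0:
            raise ValueError("detection slopes must be non-negative")

    @property
    def expected_ambiguous_rate(self) -> float:
        return self.multimap_rate * self.clear_zone_violation_rate


@dataclass
class SyntheticDataset:
    """Everything :func:`simulate` produced, including the ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    alignments: list[ReadAlignment]
    antibodies: list[AntibodyRecord]
    truth: pd.DataFrame       # per gene
    read_truth: pd.DataFrame  # per read: origin gene, decoy bookkeeping


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_gene_models(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    pos = 0
    for i in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exon_count_min, cfg.exon_count_max + 1))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(cfg.exon_length_min, cfg.exon_length_max + 1))
            exons.append(GenomicInterval("chrS", pos, pos + length, "+"))
            pos += length + cfg.intron_length
        pos += cfg.intergenic_gap
        genes.append(GeneModel(gene_id=f"SG{i:05d}", exons=exons))
    return genes


def simulate(cfg: Optional[SimulationConfig] = None) -> SyntheticDataset:
    """Draw a reproducible synthetic dataset under ``cfg``'s generative model."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = _make_gene_models(cfg, rng)
    n = cfg.n_genes
    lengths = np.array([g.exonic_length_L for g in genes], dtype=float)

    # --- expression: zero-inflated log-normal -----------------------------
    expressed = rng.random(n) >= cfg.pi_zero
    expr = np.where(expressed, rng.lognormal(cfg.log_mu, cfg.log_sigma, size=n), 0.0)

    # reads per gene proportional to abundance x length, so RPKM tracks abundance
    weights = expr * lengths
    wsum = weights.sum()
    if wsum > 0 and cfg.depth > 0:
        reads_per_gene = rng.multinomial(cfg.depth, weights / wsum)
    else:
        reads_per_gene = np.zeros(n, dtype=int)
    true_rpkm = np.where(
        wsum > 0, 1e9 * (weights / max(wsum, 1e-300)) / lengths, 0.0
    )

    # --- read alignments ---------------------------------------------------
    alignments: list[ReadAlignment] = []
    read_rows = []
    mism_vals = np.arange(len(cfg.mismatch_probs))
    read_no = 0
    decoy_span = 10_000_000
    for gi, g in enumerate(genes):
        c = int(reads_per_gene[gi])
        if c == 0:
            continue
        exon_lengths = np.array([iv.length for iv in g.exons], dtype=float)
        exon_probs = exon_lengths / exon_lengths.sum()
        exon_idx = rng.choice(len(g.exons), size=c, p=exon_probs)
        mms = rng.choice(mism_vals, size=c, p=np.asarray(cfg.mismatch_probs))
        multi = rng.random(c) < cfg.multimap_rate
        violate = multi & (rng.random(c) < cfg.clear_zone_violation_rate)
        for j in range(c):
            exon = g.exons[int(exon_idx[j])]
            start = int(rng.integers(exon.start, exon.end - cfg.read_length + 1))
            m = int(mms[j])
            hits = [
                ReadHit(
                    GenomicInterval("chrS", start, start + cfg.read_length, "+"),
                    mismatches_n=m,
                )
            ]
            n_decoys = 0
            if multi[j]:
                n_decoys = int(rng.integers(1, 4))
                for d in range(n_decoys):
                    dstart = int(rng.integers(0, decoy_span))
                    if violate[j] and d == 0:
                        # tie or inside the clear zone -> read becomes ambiguous
                        dm = m + int(rng.integers(0, cfg.clear_zone_z + 1))
                    else:
                        # safely outside the clear zone
                        dm = m + cfg.clear_zone_z + 1 + int(rng.integers(0, 3))
                    hits.append(
                        ReadHit(
                            GenomicInterval(
                                DECOY_CHROM, dstart, dstart + cfg.read_length, "+"
                            ),
                            mismatches_n=dm,
                        )
                    )
            rid = f"r{read_no:07d}"
            read_no += 1
            alignments.append(
                ReadAlignment(read_id=rid, read_length=cfg.read_length, hits=hits)
            )
            read_rows.append(
                {
                    "read_id": rid,
                    "gene_id": g.gene_id,
                    "n_decoys": n_decoys,
                    "violates_clear_zone": bool(violate[j]),
                }
            )

    # --- protein detection and the antibody panel --------------------------
    log_expr = np.log10(true_rpkm + cfg.rpkm_epsilon)
    p_ihc = _logistic(cfg.alpha_ihc + cfg.beta_ihc * log_expr)
    p_if = _logistic(cfg.alpha_if + cfg.beta_if * log_expr)
    detected_ihc = rng.random(n) < p_ihc
    detected_if = rng.random(n) < p_if

    quality = rng.choice(3, size=n, p=np.asarray(cfg.quality_probs))  # 0 good .. 2 poor
    fp_rate = np.asarray(cfg.fp_rates)[quality]
    fp_ihc = rng.random(n) < fp_rate
    fp_if = rng.random(n) < fp_rate
    ihc_present = detected_ihc | fp_ihc
    if_present = detected_if | fp_if

    wb_by_quality = [(1, 3), (4, 5), (6, 7)]
    if_by_quality = [(1, 3), (4, 6), (8, 9)]
    intensities = ("weak", "moderate", "strong")
    antibodies: list[AntibodyRecord] = []
    for gi, g in enumerate(genes):
        q = int(quality[gi])
        if ihc_present[gi]:
            tier = min(2, max(0, int(log_expr[gi] + 1)))
            intensity = intensities[tier]
        else:
            intensity = "negative"
        if if_present[gi]:
            lo, hi = if_by_quality[q]
            ifs = int(rng.integers(lo, hi + 1))
        else:
            ifs = 7
        lo, hi = wb_by_quality[q]
        wbs: Optional[int] = int(rng.integers(lo, hi + 1))
        if rng.random() < cfg.wb_missing_rate:
            wbs = None
        antibodies.append(
            AntibodyRecord(
                antibody_id=f"AB_{g.gene_id}_1",
                gene_id=g.gene_id,
                ihc_intensity=intensity,
                if_score=ifs,
                wb_score=wbs,
            )
        )
        if rng.random() < cfg.p_second_antibody:
            # a spare antibody with an independent (usually worse) IF score
            q2 = int(rng.integers(0, 3))
            lo, hi = if_by_quality[q2]
            ifs2 = 7 if not if_present[gi] else int(rng.integers(lo, hi + 1))
            lo, hi = wb_by_quality[q2]
            antibodies.append(
                AntibodyRecord(
                    antibody_id=f"AB_{g.gene_id}_2",
                    gene_id=g.gene_id,
                    ihc_intensity=intensity,
                    if_score=ifs2,
                    wb_score=int(rng.integers(lo, hi + 1)),
                )
            )

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "exonic_length_L": lengths.astype(int),
            "expressed": expressed,
            "abundance": expr,
            "reads_simulated": reads_per_gene,
            "true_rpkm": true_rpkm,
            "p_detect_ihc": p_ihc,
            "p_detect_if": p_if,
            "detected_ihc": detected_ihc,
            "detected_if": detected_if,
            "fp_ihc": fp_ihc,
            "fp_if": fp_if,
            "ihc_present": ihc_present,
            "if_present": if_present,
            "antibody_quality": quality,
        }
    )
    read_truth = pd.DataFrame(
        read_rows, columns=["read_id", "gene_id", "n_decoys", "violates_clear_zone"]
    )
    return SyntheticDataset(
        config=cfg,
        genes=genes,
        alignments=alignments,
        antibodies=antibodies,
        truth=truth,
        read_truth=read_truth,
    )


def fit_detection_logistic(
    truth: pd.DataFrame, platform: str = "ihc", rpkm_epsilon: float = 0.01
) -> dict[str, float]:
    """Recover the logistic detection parameters from a simulated truth table.

    Fits detected ~ log10(true_rpkm + eps) by maximum likelihood and returns
    the intercept and slope estimates.
    """
    import statsmodels.api as sm

    x = np.log10(truth["true_rpkm"].to_numpy() + rpkm_epsilon)
    y = truth[f"detected_{platform}"].to_numpy().astype(float)
    X = sm.add_constant(x)
    fit = sm.Logit(y, X).fit(disp=False)
    return {"alpha": float(fit.params[0]), "beta": float(fit.params[1])}


# ---------------------------------------------------------------------------
# the exact printed-counts fixture
# ---------------------------------------------------------------------------

#: Eight-way presence partition of the 2749-gene non-redundant subset.
FIXTURE_VENN = {
    "ABC": 1651, "AC": 472, "AB": 205, "BC": 120,
    "A": 110, "C": 102, "B": 55, "none": 34,
}

# supportive-score counts per group, chosen so the qualitative published
# pattern holds: IHC-only (A) and protein-only (AB) groups carry the most
# low-scoring antibodies, and the IF supportive fraction in ABC is ~3x B's.
_WB_SUPPORTIVE = {
    "ABC": 1073, "AC": 307, "AB": 62, "BC": 72,
    "A": 31, "C": 61, "B": 30, "none": 17,
}
_IF_SUPPORTIVE = {"ABC": 991, "AB": 103, "BC": 66, "B": 11}

_FIXTURE_SEED = 101_684
_FIXTURE_GENE_LENGTH = 1000


def published_counts_fixture() -> tuple[list[GeneExpression], list[ProteinCalls]]:
    """Deterministic 2749-gene expression + protein-call tables.

    Presence flags are exact integers partitioning as :data:`FIXTURE_VENN`;
    RNA-present genes get positive read counts drawn log-normally, with the
    RNA-only (C) and IF+RNA (BC) groups restricted to the lower tercile of
    that count distribution so their transcription distributions sit left
    of the full set.  Identical output on every call (fixed built-in seed).
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    log_mu, log_sigma = 3.0, 1.5
    # lower-tercile threshold of the count distribution
    from scipy import stats as _st

    tercile = float(_st.lognorm.ppf(1 / 3, s=log_sigma, scale=np.exp(log_mu)))

    group_of: list[str] = []
    gene_ids: list[str] = []
    i = 0
    for group in ("ABC", "AC", "AB", "BC", "A", "C", "B", "none"):
        for _ in range(FIXTURE_VENN[group]):
            gene_ids.append(f"G{i:04d}")
            group_of.append(group)
            i += 1

    counts: list[int] = []
    for gid, group in zip(gene_ids, group_of):
        if "C" not in group:
            counts.append(0)
            continue
        low_tail = group in ("C", "BC")
        while True:
            draw = float(rng.lognormal(log_mu, log_sigma))
            if not low_tail or draw < tercile:
                break
        counts.append(max(1, round(draw)))
    library_N = sum(counts)

    expr = [
        GeneExpression(
            gene_id=gid,
            unique_exonic_reads_C=c,
            rpkm=1e9 * c / (_FIXTURE_GENE_LENGTH * library_N),
        )
        for gid, c in zip(gene_ids, counts)
    ]

    # deterministic score assignment: the first k genes of each group get
    # supportive scores (cycling 1,2,3), the rest cycle the poorer grades.
    wb_pos: dict[str, int] = {g: 0 for g in FIXTURE_VENN}
    if_pos: dict[str, int] = {g: 0 for g in FIXTURE_VENN}
    calls: list[ProteinCalls] = []
    for gid, group in zip(gene_ids, group_of):
        ihc_present = "A" in group
        if_present = "B" in group
        j = wb_pos[group]
        wb_pos[group] += 1
        k_wb = _WB_SUPPORTIVE[group]
        wbs = (1, 2, 3)[j % 3] if j < k_wb else (4, 5, 6, 7)[(j - k_wb) % 4]
        if if_present:
            jf = if_pos[group]
            if_pos[group] += 1
            k_if = _IF_SUPPORTIVE[group]
            ifs = (1, 2, 3)[jf % 3] if jf < k_if else (4, 5, 6, 8, 9)[(jf - k_if) % 5]
        else:
            ifs = 7
        calls.append(
            ProteinCalls(
                gene_id=gid,
                antibody_id=f"AB_{gid}",
                ihc_present=ihc_present,
                if_present=if_present,
                wb_category=wb_category(wbs),
                if_category=if_category(ifs),
                wb_score=wbs,
                if_score=ifs,
            )
        )
    return expr, calls


def simulate_null_scores(
    n1: int,
    n2: int,
    score_support: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
    seed: Optional[int] = None,
    probs: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two i.i.d. ordinal score samples from one shared discrete distribution."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    support = np.asarray(score_support)
    if support.size == 0:
        raise ValueError("empty score support")
    rng = np.random.default_rng(seed)
    p = None if probs is None else np.asarray(probs)
    return (
        rng.choice(support, size=n1, p=p),
        rng.choice(support, size=n2, p=p),
    )
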