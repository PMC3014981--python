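"""Joint three-platform concordance: Venn partition, overlap rates,
association tests, expression-stratified comparisons and quantile binning.

Platform letters follow the convention A = IHC, B = IF, C = RNA-seq, so a
gene detected by RNA-seq and IF but not IHC belongs to group "BC".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ConcordanceRecord,
    GeneExpression,
    ProteinCalls,
    TestResult,
    VennCounts,
    VENN_GROUPS,
    ValidationCategory,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# table assembly and Venn partition
# ---------------------------------------------------------------------------

def build_table(
    expr: Sequence[GeneExpression], calls: Sequence[ProteinCalls]
) -> list[ConcordanceRecord]:
    """Join expression onto protein calls; the protein-call gene set is the universe.

    Genes without expression data are kept with rpkm 0 / RNA absent (logged).
    """
    expr_by_gene: dict[str, GeneExpression] = {}
    for e in expr:
        if e.gene_id in expr_by_gene:
            raise ValueError(f"duplicate gene_id in expression: {e.gene_id}")
        expr_by_gene[e.gene_id] = e
    seen: set[str] = set()
    records: list[ConcordanceRecord] = []
    n_missing = 0
    for c in calls:
        if c.gene_id in seen:
            raise ValueError(f"duplicate gene_id in calls: {c.gene_id}")
        seen.add(c.gene_id)
        e = expr_by_gene.get(c.gene_id)
        if e is None:
            n_missing += 1
        records.append(
            ConcordanceRecord(
                gene_id=c.gene_id,
                ihc_present=c.ihc_present,
                if_present=c.if_present,
                rna_present=e.rna_present if e else False,
                rpkm=e.rpkm if e else 0.0,
                wb_category=c.wb_category,
                if_category=c.if_category,
                wb_score=c.wb_score,
                if_score=c.if_score,
            )
        )
    if n_missing:
        log.info("%d genes lacked expression data; treated as RNA-absent", n_missing)
    return records


def venn(records: Sequence[ConcordanceRecord]) -> VennCounts:
    """Exact partition of genes into the eight presence patterns."""
    counts = {g: 0 for g in VENN_GROUPS}
    for r in records:
        counts[r.venn_group] += 1
    return VennCounts(counts)


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def overlap_summary(v: VennCounts) -> pd.DataFrame:
    """Headline overlap rates, each as count/denominator and percent.

    Zero denominators yield a missing percent (never 0).
    """
    ihc, if_, rna = v.marginal("A"), v.marginal("B"), v.marginal("C")
    either_protein = v.total - v["C"] - v["none"]
    both_protein = v["AB"] + v["ABC"]
    rows = [
        ("rna_presence", rna, v.total),
        ("ihc_presence", ihc, v.total),
        ("if_presence", if_, v.total),
        ("rna_coverage_of_ihc", v["AC"] + v["ABC"], ihc),
        ("rna_coverage_of_if", v["BC"] + v["ABC"], if_),
        ("all_three", v["ABC"], v.total),
        ("none", v["none"], v.total),
        ("either_protein_to_both", both_protein, either_protein),
        ("transcript_not_ihc", v["C"] + v["BC"], rna),
        ("transcript_not_if", v["C"] + v["AC"], rna),
    ]
    return pd.DataFrame(
        [
            {
                "metric": name,
                "numerator": num,
                "denominator": den,
                "percent": _pct(num, den),
            }
            for name, num, den in rows
        ]
    )


# ---------------------------------------------------------------------------
# RNA-vs-protein association
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Observed counts, rows = RNA present/absent, cols = protein present/absent."""

    observed: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.observed < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        o = self.observed
        return np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()


def contingency_rna_protein(
    records: Sequence[ConcordanceRecord], platform: Literal["ihc", "if"]
) -> ContingencyTable2x2:
    """2x2 table of RNA presence against one protein platform's presence."""
    flag = {"ihc": lambda r: r.ihc_present, "if": lambda r: r.if_present}[platform]
    o = np.zeros((2, 2))
    for r in records:
        o[0 if r.rna_present else 1, 0 if flag(r) else 1] += 1
    return ContingencyTable2x2(o)


def association_test(t: ContingencyTable2x2, correction: bool = True) -> TestResult:
    """Pearson chi-square with df=1; Yates continuity correction by default."""
    if t.total <= 0:
        raise ValueError("empty contingency table")
    if (t.expected == 0).any():
        raise ValueError("expected cell is zero; use an exact test instead")
    stat, p, dof, _ = stats.chi2_contingency(t.observed, correction=correction)
    method = "pearson_chi2" + ("_yates" if correction else "")
    return TestResult(method=method, statistic=float(stat), p_value=float(p),
                      sidedness="two_sided", df=int(dof))


# ---------------------------------------------------------------------------
# expression distributions and one-sided KS
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalCDF:
    """Right-continuous step CDF over observed values."""

    values: np.ndarray  # sorted
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        self.n = len(self.values)

    def __call__(self, x) -> np.ndarray:
        return np.searchsorted(self.values, x, side="right") / self.n


def expression_cdf_by_group(
    records: Sequence[ConcordanceRecord],
    groups: Sequence[str] = ("C", "AB", "BC", "ABC"),
) -> dict[str, EmpiricalCDF]:
    """Per-group empirical RPKM CDFs plus the full-set reference under key "all".

    Empty groups are omitted with a warning.
    """
    out: dict[str, EmpiricalCDF] = {}
    for g in groups:
        vals = [r.rpkm for r in records if r.venn_group == g]
        if not vals:
            log.warning("venn group %s is empty; omitted from CDFs", g)
            continue
        out[g] = EmpiricalCDF(np.array(vals))
    out["all"] = EmpiricalCDF(np.array([r.rpkm for r in records]))
    return out


def ks_one_sided(
    sample: Sequence[float],
    reference: Sequence[float],
    alternative: Literal["lower", "greater"] = "lower",
) -> TestResult:
    """One-sided two-sample KS test.

    ``alternative="lower"`` tests whether the sample is stochastically lower
    than the reference (its CDF lies above), via D+ = sup_x F_s(x) - F_r(x);
    ``"greater"`` uses D- = sup_x F_r(x) - F_s(x).  The p-value is the
    asymptotic one-sided tail exp(-2 D^2 mn/(m+n)).
    """
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(s) < 2 or len(r) < 2:
        raise ValueError("both samples need n >= 2")
    grid = np.union1d(s, r)
    fs = EmpiricalCDF(s)(grid)
    fr = EmpiricalCDF(r)(grid)
    if alternative == "lower":
        d = float(np.max(fs - fr))
    elif alternative == "greater":
        d = float(np.max(fr - fs))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    d = max(d, 0.0)
    m, n = len(s), len(r)
    p = min(1.0, math.exp(-2.0 * d * d * m * n / (m + n)))
    return TestResult(method="ks_two_sample_one_sided", statistic=d, p_value=p,
                      sidedness="one_sided")


# ---------------------------------------------------------------------------
# quantile-binned overlap
# ---------------------------------------------------------------------------

@dataclass
class BinnedOverlap:
    bin_index: int
    quantile_range: str
    n_genes: int
    pct_ihc_present: float
    pct_if_present: float


@dataclass
class BinOverlapResult:
    bins: list[BinnedOverlap]
    top_half: BinnedOverlap
    bottom_half: BinnedOverlap
    top_5pct: BinnedOverlap
    bottom_5pct: BinnedOverlap

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.bins])


def _slice_summary(idx: int, label: str, chunk: list[ConcordanceRecord]) -> BinnedOverlap:
    n = len(chunk)
    return BinnedOverlap(
        bin_index=idx,
        quantile_range=label,
        n_genes=n,
        pct_ihc_present=100.0 * sum(r.ihc_present for r in chunk) / n,
        pct_if_present=100.0 * sum(r.if_present for r in chunk) / n,
    )


def bin_overlap(
    records: Sequence[ConcordanceRecord],
    n_bins: int = 25,
    restrict_supportive_wb: bool = False,
) -> BinOverlapResult:
    """Protein detection rates across expression quantile bins.

    Genes are ranked by RPKM (descending; ties broken by gene id for
    determinism) and split into ``n_bins`` equal-size bins, any remainder
    spread over the top bins.  Also reports upper/lower 50% and explicit
    top/bottom 5% slices.  With ``restrict_supportive_wb`` only genes whose
    antibody has a supportive WB category enter at all.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pool = list(records)
    if restrict_supportive_wb:
        pool = [r for r in pool if r.wb_category == ValidationCategory.supportive]
    n = len(pool)
    if n < n_bins:
        raise ValueError(f"fewer genes ({n}) than bins ({n_bins})")
    ranked = sorted(pool, key=lambda r: (-r.rpkm, r.gene_id))
    base, rem = divmod(n, n_bins)
    bins: list[BinnedOverlap] = []
    pos = 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        chunk = ranked[pos : pos + size]
        label = f"top {100.0 * pos / n:.1f}-{100.0 * (pos + size) / n:.1f}%"
        bins.append(_slice_summary(i, label, chunk))
        pos += size
    half = n // 2
    n5 = max(1, round(0.05 * n))
    return BinOverlapResult(
        bins=bins,
        top_half=_slice_summary(-1, "upper 50%", ranked[:half]),
        bottom_half=_slice_summary(-2, "lower 50%", ranked[half:]),
        top_5pct=_slice_summary(-3, "top 5%", ranked[:n5]),
        bottom_5pct=_slice_summary(-4, "bottom 5%", ranked[n - n5 :]),
    )


# ---------------------------------------------------------------------------
# optional plotting
# ---------------------------------------------------------------------------

def plot_cdfs(cdfs: dict[str, EmpiricalCDF], path: str) -> None:
    """Cumulative transcription density curves on a log RPKM axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, cdf in cdfs.items():
        x = np.sort(cdf.values)
        x = x[x > 0]
        if len(x) == 0:
            continue
        style = {"all": {"color": "black", "lw": 2}}.get(label, {})
        ax.step(np.log10(x), cdf(x), where="post", label=label, **style)
    ax.set_xlabel("log10 RPKM")
    ax.set_ylabel("cumulative fraction of genes")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
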