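"""Validation-score comparisons between Venn groups and gene-set enrichment.

The KS permutation ("KS-bootstrap") test compares ordinal antibody scores
between two gene groups: the observed two-sample KS statistic is referred
to a null built by relabelling the pooled scores, which is the standard
exchangeable null for heavily tied ordinal data.  Over-representation of a
gene category inside a group is tested with the one-sided hypergeometric
tail against a user-chosen background.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ConcordanceRecord, TestResult, ValidationCategory
from .protein_calls import IF_CATEGORY_MAP, WB_CATEGORY_MAP


@dataclass
class ScoreDistribution:
    """Empirical distribution of ordinal validation scores in one group."""

    group: str
    values: list[int]            # sorted distinct score values
    counts: list[int]            # parallel to values
    n_missing: int
    supportive_fraction: float

    @property
    def n(self) -> int:
        return sum(self.counts)

    def expand(self) -> np.ndarray:
        return np.repeat(self.values, self.counts)


def score_distribution(
    records: Sequence[ConcordanceRecord],
    group: str,
    score_kind: Literal["wb", "if"] = "wb",
    category_map: Optional[Mapping[int, Optional[ValidationCategory]]] = None,
) -> ScoreDistribution:
    """Score counts and supportive fraction for one Venn group.

    Missing scores are excluded and their number reported.  For IF scores,
    grade 7 encodes absence and carries no category, so it never counts as
    supportive.
    """
    if category_map is None:
        category_map = WB_CATEGORY_MAP if score_kind == "wb" else IF_CATEGORY_MAP
    get = (lambda r: r.wb_score) if score_kind == "wb" else (lambda r: r.if_score)
    in_group = [r for r in records if r.venn_group == group]
    scores = [get(r) for r in in_group if get(r) is not None]
    n_missing = len(in_group) - len(scores)
    if not scores:
        raise ValueError(f"group {group}: no {score_kind} scores after exclusions")
    values, counts = np.unique(scores, return_counts=True)
    n_supportive = sum(
        c for v, c in zip(values, counts)
        if category_map.get(int(v)) == ValidationCategory.supportive
    )
    return ScoreDistribution(
        group=group,
        values=[int(v) for v in values],
        counts=[int(c) for c in counts],
        n_missing=n_missing,
        supportive_fraction=n_supportive / len(scores),
    )


# ---------------------------------------------------------------------------
# KS permutation test on ordinal scores
# ---------------------------------------------------------------------------

@dataclass
class BootstrapKSConfig:
    replicates_B: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replicates_B < 1:
            raise ValueError("replicates_B must be >= 1")


def _ks_stat_from_counts(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Two-sample KS statistic from per-support-value counts (vectorised over rows)."""
    f1 = np.cumsum(c1, axis=-1) / c1.sum(axis=-1, keepdims=True)
    f2 = np.cumsum(c2, axis=-1) / c2.sum(axis=-1, keepdims=True)
    return np.abs(f1 - f2).max(axis=-1)


def ks_statistic(scores1: Sequence[int], scores2: Sequence[int]) -> float:
    """Two-sided two-sample KS statistic on ordinal scores with ties."""
    support = np.union1d(scores1, scores2)
    c1 = np.array([np.sum(np.asarray(scores1) == v) for v in support], dtype=float)
    c2 = np.array([np.sum(np.asarray(scores2) == v) for v in support], dtype=float)
    return float(_ks_stat_from_counts(c1, c2))


def ks_bootstrap(
    group1_scores: Sequence[int],
    group2_scores: Sequence[int],
    cfg: Optional[BootstrapKSConfig] = None,
    method: Literal["permutation", "bootstrap", "exact"] = "permutation",
) -> TestResult:
    """Resampling null for the KS statistic on tied ordinal scores.

    ``permutation`` (default) relabels the pooled scores B times, drawing
    group-1 value counts from the multivariate hypergeometric distribution
    (exactly the label-permutation null); the p-value is the add-one
    estimator (1 + #{D* >= D_obs}) / (B + 1), so it can never be zero.
    ``bootstrap`` resamples both groups with replacement from the pooled
    empirical distribution.  ``exact`` enumerates all label assignments
    (small pooled n only) and returns the exact permutation p.
    """
    cfg = cfg or BootstrapKSConfig()
    s1 = np.asarray(group1_scores, dtype=int)
    s2 = np.asarray(group2_scores, dtype=int)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both score samples must be non-empty")
    n1, n2 = len(s1), len(s2)
    support = np.union1d(s1, s2)
    pooled_counts = np.array(
        [np.sum(s1 == v) + np.sum(s2 == v) for v in support], dtype=int
    )
    d_obs = ks_statistic(s1, s2)

    if method == "exact":
        total = math.comb(n1 + n2, n1)
        if total > 200_000:
            raise ValueError(f"exact enumeration infeasible: C({n1+n2},{n1}) = {total}")
        pooled = np.sort(np.concatenate([s1, s2]))
        hits = 0
        for pick in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            d = ks_statistic(pooled[mask], pooled[~mask])
            if d >= d_obs - 1e-12:
                hits += 1
        return TestResult(method="ks_permutation_exact", statistic=d_obs,
                          p_value=hits / total, sidedness="two_sided",
                          replicates=total)

    rng = np.random.default_rng(cfg.seed)
    B = cfg.replicates_B
    if method == "permutation":
        c1 = rng.multivariate_hypergeometric(pooled_counts, n1, size=B).astype(float)
        c2 = pooled_counts.astype(float) - c1
    elif method == "bootstrap":
        p = pooled_counts / pooled_counts.sum()
        c1 = rng.multinomial(n1, p, size=B).astype(float)
        c2 = rng.multinomial(n2, p, size=B).astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    d_null = _ks_stat_from_counts(c1, c2)
    p_val = (1 + int(np.sum(d_null >= d_obs - 1e-12))) / (B + 1)
    return TestResult(method=f"ks_{method}", statistic=d_obs, p_value=p_val,
                      sidedness="two_sided", replicates=B)


def supportive_ratio(g1: ScoreDistribution, g2: ScoreDistribution) -> float:
    """Ratio of supportive fractions between two groups (g1 / g2)."""
    if g2.supportive_fraction == 0:
        raise ValueError(
            f"group {g2.group} has no supportive antibodies; ratio undefined"
        )
    return g1.supportive_fraction / g2.supportive_fraction


# ---------------------------------------------------------------------------
# hypergeometric over-representation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentInput:
    """Counts for a one-sided over-representation test.

    background_size_Nbg: genes in the background universe.
    set_size_K: background genes annotated to the category.
    group_size_n: genes in the group of interest.
    overlap_k: annotated genes inside the group.
    """

    background_size_Nbg: int
    set_size_K: int
    group_size_n: int
    overlap_k: int
    category: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_k <= min(self.set_size_K, self.group_size_n)):
            raise ValueError("overlap_k must satisfy 0 <= k <= min(K, n)")
        if self.set_size_K > self.background_size_Nbg or self.group_size_n > self.background_size_Nbg:
            raise ValueError("K and n must not exceed the background size")


def enrichment(e: EnrichmentInput) -> TestResult:
    """One-sided hypergeometric tail P(X >= k)."""
    p = float(
        stats.hypergeom.sf(
            e.overlap_k - 1, e.background_size_Nbg, e.set_size_K, e.group_size_n
        )
    )
    return TestResult(method="hypergeometric_over_representation",
                      statistic=float(e.overlap_k), p_value=min(1.0, p),
                      sidedness="one_sided")


def enrichment_batch(inputs: Sequence[EnrichmentInput]) -> pd.DataFrame:
    """Hypergeometric p-values for many categories with BH adjustment."""
    rows = []
    for e in inputs:
        res = enrichment(e)
        rows.append(
            {
                "category": e.category,
                "background": e.background_size_Nbg,
                "set_size": e.set_size_K,
                "group_size": e.group_size_n,
                "overlap": e.overlap_k,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
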