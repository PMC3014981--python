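# Methods

## Scope and data flow

The package analyses presence concordance between a deeply sequenced
transcriptome and antibody-based protein detection in one sample. It
starts from alignment records (not raw sequence): gene models (GTF or
BED12), multi-hit read alignments with per-hit mismatch counts (SAM/BAM
with NM tags, or an equivalent TSV), and an antibody annotation table.
All coordinates are handled internally as 0-based half-open; GTF input is
converted on read and back on write, which keeps a single convention and
avoids off-by-one drift.

## RNA quantification

**Uniqueness (clear zone).** For a read with hits carrying mismatch counts,
let N\* be the minimum. The read is *unique* iff exactly one hit attains
N\*, no other hit has a mismatch count in [N\*+1, N\*+z], and N\* ≤ the
mismatch cap. Defaults: cap 3, clear zone z = 2. Ties at N\* are ambiguous
("a single location" is read literally). Reads whose best hit exceeds the
cap are discarded; hitless reads are unmapped. The implementation is
checked against an exhaustive enumeration of the rule over all hit lists of
length ≤ 4 with mismatches 0–5, and property-tested at arbitrary cap/zone.

**Assignment.** A unique read counts for a gene when its span lies entirely
inside one of the gene's exons (`single_exon`, the default — a literal
reading of exon containment, adequate for 35-bp reads) or inside a
merged-exon block (`merged_exons`, which additionally admits spans crossing
abutting exon joins). Reads contained in exons of several overlapping
genes count for each gene by default (presence is defined per gene);
`discard_shared` drops them instead. Counting is unstranded by default
(random-hexamer priming makes strandedness uncertain); strand is stored
and a stranded mode can be built on it.

**RPKM.** RPKM_g = 10⁹ · C_g / (L_g · N) with L_g the merged exon-union
length — the standard gene-length convention for RPKM — and N by default
the total number of assigned unique exonic reads (configurable, e.g. to
all uniquely mapped reads). A gene is RNA-present iff C_g ≥ 1. N = 0 is an
error ("empty library"), not a silent zero.

## Protein calls

IHC presence = intensity ∈ {weak, moderate, strong}; absent iff negative.
IF presence = validation score ≠ 7; the nine-grade scale's grade 7 means
"no staining". Note the rule is literal: grades 8–9 count as *present*
(they are poor-validation grades, not absence grades). Western-blot grades
map 1–3 → supportive, 4–5 → uncertain, 6–7 → non-supportive. The IF
score→category grouping is less standardised; the default here is 1–3
supportive, 4–6 uncertain, 8–9 non-supportive, 7 = absent (no category),
and the mapping is an argument so an alternative scheme can be substituted.

The non-redundant subset ("HPA subset") keeps genes with at least one
antibody annotated on *both* IHC and IF, choosing the antibody with the
lowest (best) IF score; ties break by lowest WB score (missing = worst),
then antibody id, so selection is fully deterministic. The selected
antibody carries all of the gene's calls — if it lacks WB data the gene's
WB category stays missing rather than borrowing another antibody's score,
keeping a strict one-antibody-per-gene correspondence.

## Concordance statistics

* **Venn partition** over A = IHC, B = IF, C = RNA-seq; counts always sum
  to the table size.
* **Overlap summary**: each rate is reported as count/denominator and
  percent; zero denominators yield an undefined percent, never 0.
* **Association**: Pearson chi-square on the 2×2 RNA-vs-platform table,
  df = 1, Yates continuity correction on by default (the corrected
  statistic is the one the headline p-value derives from; uncorrected is
  available and matches the closed form N(ad−bc)²/(r₁r₂c₁c₂)). Expected
  zeros raise an error advising an exact test.
* **One-sided KS**: D⁺ = sup (F_sample − F_ref) for the "stochastically
  lower" alternative (group CDF above the reference), evaluated over all
  pooled points; p = exp(−2D²mn/(m+n)), the asymptotic one-sided tail.
  Group-vs-all comparisons test the group against the full subset
  *including* the group (not the complement), and the direction defaults
  to "lower" because the question is whether a group contains
  lower-transcribed genes.
* **Quantile binning**: genes ranked by RPKM descending, ties broken by
  gene id (stable, reproducible bins despite many zero-RPKM ties), split
  into 25 equal-size bins with any remainder spread over the top bins.
  Because 25 equal bins are 4% each while top/bottom 5% slices are also of
  interest, both the 25-bin table and explicit upper/lower 50% and
  top/bottom 5% summaries are emitted. An optional restriction admits only
  genes whose antibody has a supportive WB category. The size-weighted
  mean of per-bin rates equals the overall rate (tested).

## Validation-score comparisons

Scores are ordinal with heavy ties, so the two-sample KS statistic is
computed on the shared support and referred to a resampling null. The
default null is pooled label permutation (the exchangeable null; drawn as
multivariate-hypergeometric counts per score value, which is exactly the
permutation distribution and vectorises well); a bootstrap mode resampling
with replacement is available, as is full enumeration for small pooled n.
The p-value uses the add-one estimator (1 + #{D\* ≥ D})/(B + 1), which is
never zero and keeps the test valid. Calibration: over 500 seeded null
pairs (n = 50 per group, uniform seven-grade scores, B = 999) the
rejection rate at α = 0.05 sits within [0.03, 0.07] (tested; the mild
conservatism comes from the discreteness of tied score data).

Over-representation of a gene category in a Venn group is the one-sided
hypergeometric tail P(X ≥ k), with Benjamini–Hochberg adjustment across a
batch. This is a deliberately plain statistic: published enrichment tools
that cluster categories and use modified Fisher scores will give different
p-values on the same counts (demonstrated in the tests), and reproducing
them is out of scope. The recommended background for subgroup analyses is
the non-redundant subset itself, since that subset is already biased
relative to all protein-coding genes.

## Synthetic data

`simulate()` draws every pipeline input from an explicit generative model:

* **Gene models**: 1–8 exons of 150–600 bp per gene laid along one
  chromosome; exons never overlap between genes, so count conservation is
  exact by construction.
* **Expression**: zero-inflated log-normal. Defaults π₀ = 0.266 (matching
  a ~73.4% genome-wide presence rate), log-mean 1.0, log-sd 1.2. Reads per
  gene are multinomial with weights abundance × length, so RPKM is
  proportional to abundance.
* **Reads**: 35 bp, placed uniformly inside a length-weighted random exon
  of the origin gene. A fraction (default 0.2) receives 1–3 decoy hits on
  a separate decoy chromosome — keeping the truth label unambiguous — and
  half of those (default) get one decoy inside the clear zone, so the
  expected ambiguous-read fraction is multimap_rate × violation_rate
  (checked to ±2 points at 10⁵ reads). True-hit mismatches are drawn over
  0–3; safe decoys sit at least z+1 mismatches above the true hit.
* **Protein detection**: P(present) = logistic(α + β·log₁₀(rpkm + ε)) per
  platform, defaults α_IHC = 1.5, β_IHC = 0.8, α_IF = 0.2, β_IF = 1.0,
  ε = 0.01. IF gets the steeper slope (its calls track transcription more
  closely), IHC the higher intercept (it calls more genes present
  overall). The slope is recoverable from a 5000-gene simulation within
  25% relative error by a logistic refit (tested; in practice within a few
  percent). Note the logistic floor leaves silent genes a non-trivial
  IHC detection probability; together with antibody false positives this
  emulates unspecific staining, and it means the poor-antibody signal
  concentrates most visibly in the protein-only (AB) group, as the
  validation-score analysis on simulated data shows.
* **Antibodies**: a latent quality band (good/medium/poor, 60/25/15%)
  drives both the scores (WB 1–3/4–5/6–7, IF 1–3/4–6/8–9) and a
  false-positive staining rate (2/10/35%) that is OR-ed into the presence
  calls, so poorly validated antibodies generate spurious presence —
  the mechanism the validation-score comparisons are designed to expose.
  ~30% of genes get a second antibody to exercise best-antibody selection.

What the generator does **not** emulate: sequencing error or colorspace
chemistry, splice-junction reads, fragment-level biases (GC, positional),
gene–gene overlap on the genome, correlated antibody cross-reactivity
(false positives are independent per platform), and real validation-score
marginals. Passing tests on synthetic data therefore demonstrate internal
consistency and statistical behaviour of the pipeline, not fidelity of any
particular biological claim.

`published_counts_fixture()` is different in kind: it is the deterministic 2749-gene
presence table whose eight-way partition equals the published study counts
exactly (integer flags, fixed built-in seed), so every statistic derivable
from those printed counts is recomputed, not asserted. RPKM values for the
RNA-only and IF+RNA groups are drawn from the lower tercile of the count
distribution, making their transcription distributions sit left of the
full set (qualitatively, as observed); validation scores are laid out so
the supportive fraction is lowest in the IHC-only and protein-only groups
and the IF supportive ratio between the all-three and IF-only groups is
3.0. Only the count-derived statistics are quantitative reproductions;
expression- and score-distribution shapes are qualitative constructions.

## Problem sizes and numerical choices

Default simulation sizes (2000 genes / 2×10⁵ reads in the analysis
scripts; 5000 genes for parameter-recovery checks; 10⁴ permutation
replicates) were chosen so each stage completes in seconds on one core
while leaving Monte-Carlo error well below the effect sizes examined. KS
statistics compare with a 10⁻¹² slack when counting null exceedances to
make ties robust to floating-point noise. All randomness flows through
`numpy.random.default_rng` seeds; the pipeline orchestrator derives
per-stage seeds from one top-level seed, and rerunning with the same seed
reproduces byte-identical tables.

## Known limitations

* The asymptotic one-sided KS p-value is anti-conservative for very small
  samples; for ordinal scores use the permutation test instead.
* The IF score→category grouping and the "best antibody" ordering are
  configurable conventions, not published constants.
* Junction-spanning reads are only assignable in `merged_exons` mode and
  only across abutting blocks; true split alignment is out of scope.
* The hypergeometric enrichment is not comparable to clustering-based
  enrichment tools' output on the same input.
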