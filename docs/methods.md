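# Methods

This note documents the models, defaults and numerical choices behind
lightomics, and what the synthetic-data experiments do and do not show.

## Study design being modelled

Detached *Cuscuta campestris* shoots are exposed to red-enriched (R) or
far-red-enriched (FR) light; shoots harvested before transfer serve as the
natural-light reference (Ctrl). Sequenced time points are 23 h (day 1) and
71 h (day 3) with four replicates per condition; mRNA counts cover all
five groups, while the sRNA and bisulfite layers cover the day-3 R and FR
groups. The package consumes gene-level counts, per-cytosine methylation
reports, locus-level sRNA counts, a genome annotation and two input maps
(gene → functional bin, miRNA family → target genes); read processing and
alignment are upstream of this artifact.

## Differential expression

The engine is a deliberately simple negative-binomial Wald test, not a
shrinkage estimator: counts are scaled by median-of-ratios size factors
(geometric-mean reference over genes positive in every sample); the
per-gene dispersion α is the method-of-moments estimate
(s² − m̄)/m̄², averaged over the two groups and floored at 10⁻⁸; the Wald
statistic is the log mean ratio over its delta-method standard error
√(Σ_g (m̄_g + α m̄_g²)/(n_g m̄_g²)). The statistic is referred to a *t*
distribution with Welch–Satterthwaite degrees of freedom rather than a
normal: at n = 4 replicates the normal reference is visibly
anticonservative, while the t reference holds the raw-p type-I rate at
0.04–0.05 in the 10 000-gene null simulation the acceptance suite runs.
Because the flooring makes the variance max(s², m̄), the test is never
more liberal than a Welch t-test on the normalized counts. Groups with a
zero mean get half a normalized count added on both sides of the ratio;
exact ratios are preserved whenever both means are positive. Gates are
BH FDR q ≤ 0.05 and |log₂FC| ≥ 1.5 (the printed minimum fold-change
criterion; the "three-fold" phrasing that appears alongside it is treated
as a rounding of 2^1.5 ≈ 2.83). The same engine, with library-total size
factors, tests miRNA-family and per-size-class sRNA differential
accumulation — the statistical test for sRNA shifts at DMRs is not
specified by the study design and this reuse is our choice.

## Soft clustering and FR-DEG construction

Genes qualify for clustering when differentially expressed in at least one
pairwise group contrast and carrying ≥ 5 normalized counts in ≥ 3 samples.
Profiles are log₂(x+1) of **size-factor-normalized counts**, z-scored per
gene. The classical choice is log₂(TPM); per-gene z-scoring cancels the
gene-length factor exactly, so the two differ only in the per-sample
scaling — and TPM's total-count scaling carries a composition bias that
matters here: with 30 % of a 200-gene transcriptome planted as regulated,
the library-mass shift between groups moved FR-vs-R centroid differences
of light-general archetypes by ≈ 0.5 z, past the labelling threshold.
Median-of-ratios scaling is the standard robust alternative and is used
for clustering and network profiles throughout (TPM is still computed,
written, and contract-tested).

Fuzzy c-means uses the alternating update equations (memberships ∝
d^(−2/(m−1)), centroids as u^m-weighted means), k-means++ seeding from the
master seed, 10 restarts keeping the best objective, and asserts at every
iteration that the objective Σ u^m d² never increases. The fuzzifier m
defaults to the Schwämmle–Jensen empirical rule from (N genes,
D dimensions); for replicate-level profiles (D = 20) it lands near 1.1–1.3,
giving near-crisp memberships. Genes are retained at membership ≥ 0.7 and
hard-assigned to their argmax cluster (ties to the lowest index). A
cluster is FR-up when its centroid's FR-minus-R mean exceeds δ = 0.5 z on
day 1, day 3 or both (and never the opposite); FR-down mirrored; mixed or
flat centroids are "other". Note the rule — like any FR-vs-R contrast —
cannot distinguish "down in FR" from "up in R"; the generator's truth
labels use the same semantics. Redundant clusters merge by single linkage
over centroid Pearson correlation ≥ 0.8 with test p < 0.05. The FR-DEG
set is the union of members of FR-labelled clusters.

## Co-expression networks

Pairwise Pearson correlations within the FR-up and FR-down sets are
Fisher-transformed (atanh), standardized over all pairs, and kept as edges
when the standardized value reaches Φ⁻¹(0.945) ≈ 1.5982 **and** the raw
PCC reaches the per-set floor (0.98 up / 0.97 down). The two filters'
interplay is unstated in the original description, so both are applied
conjunctively and the retained fraction is reported for the quantile step
alone and for the combination, along with the PCC threshold the quantile
implies. Only positive correlations form edges by default. On the default
synthetic data replicate-level noise caps within-archetype correlations
near 0.93, so the strict floors leave the hub networks nearly empty —
faithful defaults, sparse synthetic networks; the null-calibration tests
therefore disable the floor. Shortest paths to hubs break ties fully
lexicographically (nearest hub first, then smallest node sequence).

## Enrichment

Hypergeometric upper tail (scipy) per bin over the universe of annotated
genes, BH across the tested bins of one query set (jointly across
hierarchy levels), enriched at FDR ≤ 0.05. `gene_ratio` is k/K — query
genes with the term over universe genes with the term. Depletion is not
tested. BH is statsmodels' `fdr_bh` behind a shared `bh_adjust` surface;
note BH adjustment is *not* idempotent in general (p = [0, 0.5, 1] is a
counterexample), so the tests assert monotonicity and the naive-reference
equality instead.

## Methylome

Methylation level is m/(m+u) per cytosine; global levels are
pooled-count ratios Σm/Σ(m+u), not means of per-site levels. Metagene
profiles rescale each gene body to 20 bins with fixed-width 2-kb flanks,
mirror minus-strand genes by exact coordinate reflection (making strand
symmetry bit-exact), and pool counts per bin across genes; genes shorter
than the bin count are skipped and counted. The DMR caller replaces
binary-segmentation callers with a transparent two-step: candidate
regions are maximal runs of same-context cytosines covered in both
conditions with inter-cytosine gaps ≤ 300 bp; per-candidate, the
replicate-pooled per-site levels of the two conditions are compared by
two-sided Mann–Whitney U, BH-corrected per context across candidates.
Reported DMRs must satisfy all three printed filters — > 5 covered
cytosines, |pooled difference| > 0.1, q < 0.05 — and this is asserted on
every run. Promoters are the strand-aware 2-kb window upstream of the
TSS, clipped at contig ends, a configurable definition. Feature overlap
uses ≥ 1 bp on half-open intervals; a DMR may carry several feature labels
and is classed gene-only / TE-only / both / neither from gene-body vs TE
overlap.

## sRNA layer

Size classes are fixed to 18–28 nt (a 16-nt floor is enforced on input);
RPM divides by the per-sample genome-matching 18–28-nt total.
Categorization assigns each read once, to the first matching index in
gene → miRNA → TE → rRNA → tRNA order ("other" otherwise); an
`independent` mode reports overlapping totals instead, since the original
sequential-alignment wording admits both readings. sRNA abundance at DMRs
sums the counts of all loci a DMR overlaps and is tested per size class
(21/22/24 nt) with the NB engine; BH runs across regions within a size
class, and direction (up/down) is taken at q ≤ 0.05.

## RdDM integration

Each (FR-DEG, DMR) pair overlapping the gene's promoter, exon or intron
becomes a record (the feature with the largest overlap is kept; ties
promoter > exon > intron). The consistency rule: hypermethylation with
sRNA gain in ≥ 1 of the 21/22/24-nt classes and expression loss, or the
fully mirrored triple; non-significant sRNA never supports consistency.
Expression direction comes from the FR-DEG cluster label, not a re-test.
A gene is RdDM-consistent when any of its records is; the candidate
report lists all of a consistent gene's DMRs, flagging the sRNA-silent
ones, plus hub-network membership.

## The synthetic experiment

The generator emulates the study conditions, not any particular dataset.
One chromosome is a lattice of 150-bp random-ACGT "cytosine islands"
separated by 400-bp A/T spacers; since the spacer exceeds the DMR
caller's maximum gap, candidate regions coincide with islands and every
planted DMR is recoverable by an idealized caller. Gene bodies span 1–3
lattice units (terminal islands are exons, the middle an intron), strands
alternate, TEs may overlap gene bodies. Defaults: 200 genes, 60 planted
DEGs (log₂FC ~ U(2, 3), above the 1.5 gate so planted effects are
recoverable at n = 4) spread over ten temporal archetypes (FR up/down at
day 1, day 3, both; R-specific; light-general), NB dispersion 0.05,
baseline means log-normal around 100 with planted genes floored at 50 so
the planted contrast is detectable. Methylation baselines CG 0.7 / CHG 0.5
/ CHH 0.1 are arbitrary plumbing defaults (not empirical values), coverage
Poisson(20) per pooled condition, 200 planted DMRs of effect 0.4 (80 %
CHH); hypomethylation raises the R level instead of clipping FR at zero,
so the full effect survives in the low-CHH baseline, and any clipping is
recorded as the effective effect in the truth file. 12 RdDM genes pair an
FR-down gene with a hyper DMR (or FR-up with hypo) on an island private to
that gene — shared promoter islands between neighbours would otherwise
create ambiguous planted pairs — plus matching 4-fold 21/22/24-nt sRNA
shifts. Each generator draws from its own RNG stream derived from the
master seed by a fixed offset, so outputs are bit-reproducible and adding
a generator never perturbs the others.

What passing tests show: the statistical kernels match independent
oracles; the engines are calibrated and powered under NB/binomial noise at
the study's replicate numbers; planted signals of the stated sizes are
recovered through the full pipeline. What they do not show: robustness to
features of real data the generator omits — pooling variance across
biological replicates, gene-length and GC biases, bisulfite conversion
error, overlapping transcripts, genome-scale multiple-testing burdens, or
real annotation geometry.

Two recovery regimes are exercised. Under the default (noisy) config the
sRNA-at-DMR test runs over both RdDM and background DMRs at FR-DEGs, and
BH FDR control admits an occasional chance-significant null direction —
so the end-to-end guarantee is sensitivity ≥ 0.8. The noise-controlled
regime (`background_dmrs_at_degs=False`, 8-fold sRNA shifts) keeps
background DMRs away from genes so planted margins exceed every test
threshold; there recovery is exact (sensitivity 1.0, zero false flags).

## Problem sizes and numerics

Default test/acceptance sizes: 200-gene pipeline runs (~10 s each),
10 000-gene DE calibration, 20 × (200 genes × 10 samples) network nulls,
and the full ≤ 12-item hypergeometric enumeration — chosen so the whole
suite and the acceptance script each run in about a minute on one CPU.
Convergence: fuzzy c-means stops at centroid shift < 10⁻⁶ (≤ 300
iterations); correlations at |r| ≥ 1 are clamped to 1 − 10⁻¹² with a
warning before atanh; Mann–Whitney U falls back to p = 1 when all levels
tie; TPM of an all-zero sample is an all-zero column with a warning.
Known limitations: no dispersion shrinkage or independent filtering in
the DE engine; no consensus clustering or automatic cluster-number
selection; the DMR caller does not segment within a candidate region, so
a region mixing opposite shifts would dilute; miRNA target prediction,
read alignment and bisulfite processing are out of scope by design.
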