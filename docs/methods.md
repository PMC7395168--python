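# Methods

## Data model

All computations run on a genotype matrix of accessions × bi-allelic SNP
markers with four call states: homozygous reference, heterozygous,
homozygous alternate, missing. The state model is ref/alt-relative rather
than nucleotide strings because every downstream statistic needs only
allele counts; nucleotide rendering ("AA"/"AG"/"GG", "XX"/"XY"/"YY",
0/1/2) is a dialect concern of the table reader, declared per file.
Coordinates are 1-based closed, matching VCF. Accessions carry a predefined
population label (from a declared set, plus "unknown") and a type (F1,
breeding line, landrace, unknown); breeding lines and landraces are treated
as inbred accessions throughout.

## Quality control

Marker statistics are computed over gene copies: a heterozygote contributes
one copy of each allele and missing calls contribute nothing, so MAF
= min(p, 1−p) with p the alternate-copy fraction among called copies. A
marker with zero called genotypes gets an undefined (NaN) MAF and is
flagged, never silently reported as monomorphic.

Marker filters use *strict* inequalities by default — keep iff
MAF > 0.05 and missing rate < 0.10 — so boundary markers (MAF exactly
0.05) are dropped; a flag switches to inclusive comparisons. Sequencing
depth is not part of this data model; when a VCF carries DP an upstream
pre-filter can honor it, but the matrix itself never does.

Sample filtering excludes accessions whose call rate falls strictly below a
threshold. The default is 0.65 rather than 0.90: in array-based germplasm
assays the failure mode is bimodal — catastrophic assay failures in the
30–60% band versus mildly degraded samples above 80% — and a 0.65 cut
removes the former while retaining the latter, which are still informative
for diversity statistics. 0.90 remains available as a strict preset.

Substitution types are classified on the unordered allele pair:
{A,G} and {C,T} are transitions, the other four pairs transversions, with
subtypes canonicalized to A/G, C/T, A/T, A/C, G/T, C/G.

## Diversity and differentiation estimators

**PIC** per marker: `1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`; for two alleles
`1 − p² − q² − 2p²q²`. Per-population PIC is averaged over *all* markers
(monomorphic markers contribute 0) by default; a flag restricts the
average to markers polymorphic within the population. The default was a
genuinely open choice — software in this space differs — and averaging over
all markers keeps per-population values comparable on a common marker set.

**Expected heterozygosity** uses Nei's unbiased small-sample correction,
`He = 2n/(2n−1) · (1 − Σ p_i²)` with n the called diploid count at the
marker; undefined below two called diploids. Population He is the mean over
markers.

**Allelic richness** is the rarefaction estimator
`A = Σ_i [1 − C(N−N_i, g)/C(N, g)]` — the expected number of distinct
alleles in a hypergeometric draw of g gene copies — evaluated with
log-gamma arithmetic, with C(a,b) = 0 when a < b. The common rarefaction
size g defaults to the minimum called gene-copy count over (marker,
population), floored at 2, so every marker is comparable across
populations; a per-marker adaptive mode is available. Because g tracks the
worst-genotyped marker, reported A values shrink as missingness grows.

**Weir–Cockerham θ** is computed from genotype data (not allele counts
alone), so the within-individual component c uses observed heterozygote
frequencies and no Hardy–Weinberg assumption enters the estimator — 
essential here, since the collections mix fully inbred lines with F1
hybrids. Per locus the two-population 1984 variance components a, b, c are
computed with the unequal-sample-size n̄ and n_c terms; the multi-locus
estimate is the ratio of sums Σa / Σ(a+b+c), not the mean of per-locus
ratios (the latter is badly behaved at low-information loci). Loci with no
called genotype in either population are excluded and counted. Negative
estimates are reported as computed; display layers may show them as ≤ 0.

**Permutation test**: the permutation unit is the accession — its full
multilocus genotype moves with its label — preserving within-individual
structure. For each population pair, labels are permuted within the pair's
pooled accessions; `p = (1 + #{θ_perm ≥ θ_obs}) / (1 + P)` with P
permutations (default 10,000), so p is never zero and is bounded below by
1/(P+1). Bonferroni correction multiplies over the pairs actually tested
(6 for four populations). Identical seeds give bit-identical p-values.

**Nei's D** follows the 1978 sample-size-corrected formulation:
within-population identities `J = (2n Σp_i² − 1)/(2n − 1)` per locus,
between-population identity `J_xy = Σ p_i q_i`, all averaged over the loci
defined in both populations, then `D = −ln(J_xy/√(J_x J_y))`. When the
normalized identity is ≤ 0 (e.g. fixed differences at every locus) D is
reported as infinite rather than raising. With few diploids the unbiased
correction can push D slightly negative for identical populations; this is
a property of the estimator, not an error.

## Structure analysis

Genotypes are encoded as alternate-allele dosage 0/1/2 with per-marker mean
imputation of missing cells (imputed cells are masked so they can be
audited); all-missing markers are dropped with a warning. PCA is
column-centered without unit-variance scaling — the convention of the
standard R workflow this mirrors (`prcomp`-style on dosages) — computed by
full SVD, with component signs fixed by forcing each component's
largest-magnitude loading positive. Euclidean distances are taken on the
imputed dosage rows so every accession pair is comparable; UPGMA
(average linkage) merge heights are the linkage distances themselves, the
`hclust` convention (a 3-leaf example with d(A,B)=2, d(A,C)=d(B,C)=4 merges
A,B at height 2 and joins C at height 4). Tree cuts that cannot yield
exactly k clusters because of tied merge heights raise an error naming the
nearest attainable k.

The published workflow assigns accessions to clusters in PC space by eye;
to make that computable, the package runs seeded k-means (k = 4 by
default) on the first two PCs and reports it alongside the UPGMA cut. The
two clusterings are compared after an optimal one-to-one label matching
(Hungarian assignment on the contingency table); discordant accessions are
those off the matched diagonal.

## Panel selection and identification

Candidate markers need a PIC at or above the floor (default 0.3,
inclusive). Panel slots are apportioned to chromosomes proportionally to
chromosome length by largest-remainder rounding; each chromosome is split
into that many equal-length bins and the max-PIC marker per bin is chosen
(ties to the earlier position). Empty bins release their slots to the best
unchosen markers on the same chromosome; slots a chromosome cannot fill
move to the globally best remaining eligible markers. Nested subsets rank
the parent panel by PIC (ties by chromosome then position) and then repair
coverage: while some chromosome present in the parent is empty and another
holds ≥ 2 selected markers, the empty chromosome's best marker replaces
the worst marker of an over-represented chromosome. Both schemes are stated
interpretations — the original construction's exact rules are not
recoverable — and alternates (pure PIC rank, pure spacing) remain
selectable through the same interfaces.

Identification: two accessions are *distinct* iff at least one panel marker
shows two non-missing, differing calls. The default policy is conservative
— missingness never distinguishes — so call-rate artifacts cannot inflate
identification rates; a strict policy (missing vs called counts as
different) exists for sensitivity analysis. An accession is *identified*
iff distinct from every other accession, and the identification rate is
identified / total. Because "not distinct" need not be transitive under
missingness, indistinguishable groups are reported as connected components
of that relation, with pairwise detail available.

## Synthetic germplasm generator

The simulator exists to validate the estimators, and its defaults encode
the study conditions the analysis assumes. Ancestral allele frequencies are
Uniform(0.05, 0.95) per marker; each population's frequencies follow the
Balding–Nichols beta distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)` with
divergence F (F = 0 short-circuits to the ancestral frequencies — the
model's no-divergence limit). Inbred lines are fully homozygous (infinite
selfing; a residual-heterozygosity option exists), drawn allele-by-allele
from the population frequencies. Intraspecific F1s cross two distinct
random lines from one population's pool; interspecific F1s cross lines from
two named populations and form their own labelled population. Markers are
unlinked and placed uniformly on the chromosomes. Noise is applied last:
per-cell missingness, whole-sample call-rate failures (a failed sample
loses a large fraction of its calls), and symmetric dosage-flip genotype
errors. All randomness flows from one seed; identical seeds give
bit-identical collections.

The pumpkin-shaped preset has four populations sized 73/63/45/31 and 224
markers on 20 chromosomes. The species populations split into inbreds and
intraspecific F1s (inbreds + F1s: maxima-like 33+40, moschata-like 28+35,
pepo-like 24+21 — 85 inbreds and 96 intraspecific F1s in total, matching
the real collection's composition at the totals level); the
fourth population is 31 interspecific F1s crossed from the first two
species' line pools. Divergences (0.50, 0.50, 0.35) were fixed once so the
two crossing species are the most differentiated pair, as in the real
collection; the interspecific hybrids then show the highest expected
heterozygosity automatically, because they are heterozygous wherever the
parental species are near-fixed for different alleles. Missingness 0.02 and
genotype-error rate 0.005 represent a well-behaved array assay.

What the generator does *not* emulate: linkage and recombination (markers
are exchangeable given frequencies), shared pedigree among F1 cultivars
beyond a finite line pool, ascertainment bias of array markers toward one
reference genome, and locus-specific error structure (secondary SNPs under
primer sites). Passing tests on simulated data therefore demonstrate
estimator correctness and pipeline behavior under the stated model, not
the real collection's exact table values — those require its published
genotype matrix.

## Problem sizes in validation

The parameter-recovery suite uses two populations of 50 inbreds at 500
markers, 50 replicates per divergence value, which bounds the Monte-Carlo
standard error of the mean θ well below the ±0.02 acceptance band; the
null-calibration run uses 999 permutations × 100 replicates, giving a
binomial standard error of ~2 points on the rejection rate. The
pumpkin-shaped runs use the preset exactly as stated above.

## Known limitations

- Only bi-allelic SNPs are modelled; multi-allelic records are dropped at
  ingestion (counted and logged), and the PIC/He/richness code paths accept
  general allele-frequency vectors only at the scalar level.
- The Weir–Cockerham implementation covers population pairs (r = 2), the
  only case the analysis needs; there is no global multi-population θ.
- No AMOVA, linkage disequilibrium, kinship, or model-based ancestry
  inference; the workflow this package reproduces uses none.
- Nei's D at small sample sizes can be slightly negative for
  near-identical populations (unbiased-estimator property).
- The exact marker lists of the published 400/192/96/48/24/12 panels are
  not recoverable from the publication, so panel construction here is a
  faithful-by-intent interpretation; only properties that are invariant to
  the exact subset (monotonicity of the identification cascade, coverage,
  the full-panel rate) are treated as reproducible.
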