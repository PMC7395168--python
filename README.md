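# pumpkinpop

SNP-marker analysis of cultivated pumpkin (*Cucurbita* spp.) germplasm —
and of any comparable crop collection genotyped on a bi-allelic SNP panel.
The package takes a diploid genotype matrix (VCF or a delimited
accession × marker table), applies the marker- and sample-level QC used for
array-genotyped germplasm panels, quantifies diversity within and
differentiation between predefined populations, resolves population
structure with PCA and UPGMA clustering, and builds genome-distributed core
marker panels scored by a variety-identification statistic relevant to DUS
(distinctness, uniformity, stability) testing. A synthetic-germplasm
simulator with full truth records makes every stage testable without
external data.

## Statistics implemented

For a marker with allele frequencies $p_i$ estimated over called gene
copies (a heterozygote contributes one copy of each allele):

- **PIC** (polymorphic information content):
  $\mathrm{PIC} = 1 - \sum_i p_i^2 - \sum_{i<j} 2 p_i^2 p_j^2$
- **Unbiased expected heterozygosity** (Nei's small-sample correction, $n$
  called diploids): $H_e = \frac{2n}{2n-1}\left(1 - \sum_i p_i^2\right)$
- **Allelic richness** by hypergeometric rarefaction to $g$ gene copies:
  $A = \sum_i \left[1 - \binom{N-N_i}{g} / \binom{N}{g}\right]$
- **Pairwise $F_{st}$**: Weir & Cockerham's (1984) $\theta$ from the
  genotype-level variance components $a$ (among populations), $b$ (among
  individuals within populations) and $c$ (within individuals), combined
  across loci as $\hat\theta = \sum_\ell a_\ell / \sum_\ell (a_\ell + b_\ell
  + c_\ell)$, with an accession-level permutation test and Bonferroni
  correction over the population pairs tested
- **Nei's standard genetic distance** (1978, corrected for sample size):
  $D = -\ln\left(J_{xy} / \sqrt{J_x J_y}\right)$ with unbiased
  within-population identities $J = (2n\sum p_i^2 - 1)/(2n-1)$
- **Identification rate**: the fraction of accessions whose multilocus
  genotype over a marker panel differs (both calls present, calls unequal)
  from every other accession's

## Worked example

Simulate a pumpkin-shaped collection (four populations sized 73/63/45/31:
three species-like populations of inbreds plus intraspecific F1s, and 31
interspecific F1 hybrids; 224 markers on 20 chromosomes) and run the full
pipeline:

```sh
pumpkinpop simulate --seed 2 --out-dir sim
# wrote 212 accessions x 224 markers to sim
pumpkinpop run-all --genotypes sim/genotypes.vcf \
    --populations sim/populations.tsv --permutations 10000 --seed 2 --out-dir out
# pipeline complete; reports in out
pumpkinpop identify sim/genotypes.vcf --out id.tsv
# 212/212 accessions identified (100.0%); wrote id.tsv
```

`out/` then holds the QC report, a differentiation matrix (Nei's D upper
triangle, $\theta$ with significance stars lower triangle), a per-population
diversity table, PCA scores, the UPGMA tree in Newick, cluster assignments
with UPGMA-vs-PCA discordance, and the core-panel/identification reports.
On this simulated collection (seed 1) the two crossing species are the most
differentiated pair ($\theta = 0.52$, $D = 0.28$), all six pairwise
permutation tests are significant at $P < 0.001$ after Bonferroni
correction, the interspecific hybrids are the most diverse population
($H_e = 0.28$ against 0.18–0.23 for the species populations), and the
nested 192/96/48/24/12-marker panels identify 100/100/100/97.2/62.7% of
accessions — an identification cascade monotone in panel size. Each of
those numbers is a property of the simulated data, not of the real
collection; the real collection's values require its genotype table (above).

The same stages are importable as a library (`pumpkinpop.qc`,
`pumpkinpop.popgen`, `pumpkinpop.structure`, `pumpkinpop.panel`,
`pumpkinpop.simulate`, `pumpkinpop.pipeline`).

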