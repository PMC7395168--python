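"""Diversity and differentiation statistics for bi-allelic SNP data.

Implements, per marker and per population:

* PIC (polymorphic information content),
  ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``;
* unbiased expected heterozygosity, ``He = 2n/(2n-1) * (1 - sum(p_i^2))``
  with n the number of called diploids (Nei's small-sample correction);
* allelic richness by hypergeometric rarefaction to a fixed gene-copy count;
* Weir & Cockerham's (1984) theta from genotype variance components a/b/c,
  combined across loci as a ratio of sums, with an accession-level
  permutation test and Bonferroni correction over population pairs;
* Nei's (1978) standard genetic distance corrected for sample size.

All estimators treat a heterozygote as contributing one copy of each allele
and exclude missing calls from gene-copy counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, PopulationMap, ValidationError


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class AlleleFrequencySpectrum:
    """Per-marker alt-allele frequency and gene-copy count for one population.

    ``p_alt`` is NaN where no gene copies were observed (flagged undefined).
    """

    marker_ids: list[str]
    p_alt: np.ndarray          # NaN where undefined
    gene_copies: np.ndarray    # 2 * called diploids
    n_het: np.ndarray          # observed heterozygote counts

    @property
    def n_called(self) -> np.ndarray:
        return self.gene_copies // 2

    @property
    def defined(self) -> np.ndarray:
        return self.gene_copies > 0


def allele_frequencies(
    matrix: GenotypeMatrix, accession_subset: Sequence[str] | None = None
) -> AlleleFrequencySpectrum:
    """Alt-allele frequencies over called gene copies in an accession subset."""
    if accession_subset is not None:
        if len(accession_subset) == 0:
            raise ValidationError("accession subset is empty")
        calls = matrix.calls[matrix.accession_index(accession_subset), :]
    else:
        calls = matrix.calls
    n_het = (calls == HET).sum(axis=0)
    n_hom_alt = (calls == HOM_ALT).sum(axis=0)
    n_called = (calls != MISSING).sum(axis=0)
    copies = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(copies > 0, (2 * n_hom_alt + n_het) / copies, np.nan)
    return AlleleFrequencySpectrum(
        list(matrix.marker_ids), p_alt, copies.astype(int), n_het.astype(int)
    )


# ---------------------------------------------------------------------------
# marker informativeness / diversity


def pic(freqs: np.ndarray) -> float:
    """PIC for one marker from its allele-frequency vector (any allele count)."""
    p = np.asarray(freqs, dtype=float)
    if np.isnan(p).any():
        return float("nan")
    sq = p ** 2
    cross = 0.0
    for i in range(len(p) - 1):
        cross += 2.0 * np.sum(sq[i] * sq[i + 1:])
    return float(1.0 - sq.sum() - cross)


def pic_biallelic(p_alt: np.ndarray) -> np.ndarray:
    """Vectorized PIC over markers: 1 - p^2 - q^2 - 2 p^2 q^2."""
    p = np.asarray(p_alt, dtype=float)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def expected_het_unbiased(p_alt: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Nei's unbiased expected heterozygosity per marker.

    He = 2n/(2n-1) * (1 - p^2 - q^2); undefined (NaN) for n_called < 2.
    """
    p = np.asarray(p_alt, dtype=float)
    n = np.asarray(n_called, dtype=float)
    raw = 1.0 - p**2 - (1.0 - p) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        he = np.where(n >= 2, (2 * n / (2 * n - 1)) * raw, np.nan)
    return he


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k) with -inf where n < k (so the ratio C(N-Ni,g)/C(N,g) -> 0)."""
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    out[ok] = gammaln(n[ok] + 1) - gammaln(k + 1) - gammaln(n[ok] - k + 1)
    return out


def allelic_richness(allele_copy_counts: np.ndarray, g: int) -> float | np.ndarray:
    """Rarefaction allelic richness at gene-copy sample size ``g``.

    ``allele_copy_counts`` is either a 1-D vector of per-allele copy counts
    for one marker, or a (markers, alleles) array. The estimator is
    A = sum_i [1 - C(N - N_i, g) / C(N, g)], the expected number of distinct
    alleles in a hypergeometric draw of g copies.
    """
    counts = np.atleast_2d(np.asarray(allele_copy_counts, dtype=float))
    N = counts.sum(axis=1)
    if g < 1:
        raise ValidationError(f"rarefaction size g={g} must be >= 1")
    too_small = N < g
    if too_small.any():
        bad = int(np.argmax(too_small))
        raise ValidationError(
            f"g={g} exceeds total gene copies N={int(N[bad])} at marker index {bad}"
        )
    log_den = _log_comb(N, g)[:, None]
    log_num = _log_comb(N[:, None] - counts, g)
    ratio = np.exp(log_num - log_den)
    A = (1.0 - ratio).sum(axis=1)
    if np.asarray(allele_copy_counts).ndim == 1:
        return float(A[0])
    return A


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


@dataclass
class PairwiseDifferentiation:
    """Fst (theta) + Nei's D between one population pair."""

    pop_a: str
    pop_b: str
    theta: float
    a_sum: float
    b_sum: float
    c_sum: float
    nei_D: float = float("nan")     # np.inf when identity I <= 0
    p_value: float = float("nan")
    bonferroni_significant: bool = False
    n_loci_used: int = 0
    n_loci_excluded: int = 0


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components for two populations.

    n_i: called diploid counts; p_i: alt-allele frequencies; h_i: observed
    heterozygote *frequencies* (het count / n_i). Vectorized over loci.
    """
    r = 2
    n_tot = n1 + n2
    nbar = n_tot / r
    nc = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / n_tot
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _pop_locus_summaries(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, p_alt, h_obs) per locus for a genotype sub-array; NaN where n=0."""
    n_het = (calls == HET).sum(axis=0)
    n_alt = (calls == HOM_ALT).sum(axis=0) * 2 + n_het
    n = (calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, n_alt / (2 * n), np.nan)
        h = np.where(n > 0, n_het / n, np.nan)
    return n.astype(float), p, h


def _theta_from_calls(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n1, p1, h1 = _pop_locus_summaries(calls_a)
    n2, p2, h2 = _pop_locus_summaries(calls_b)
    # a locus is usable when both populations have calls and nbar > 1
    usable = (n1 > 0) & (n2 > 0) & ((n1 + n2) > 2)
    a = np.zeros(calls_a.shape[1])
    b = np.zeros_like(a)
    c = np.zeros_like(a)
    if usable.any():
        a[usable], b[usable], c[usable] = _wc_components(
            n1[usable], p1[usable], h1[usable], n2[usable], p2[usable], h2[usable]
        )
    denom = a[usable].sum() + b[usable].sum() + c[usable].sum()
    theta = a[usable].sum() / denom if denom != 0 else float("nan")
    return theta, a, b, c, usable


def pairwise_fst(
    matrix: GenotypeMatrix, pop_a: Sequence[str], pop_b: Sequence[str],
    labels: tuple[str, str] = ("A", "B"),
) -> PairwiseDifferentiation:
    """Multi-locus Weir-Cockerham theta between two accession groups.

    Theta is the ratio of summed components sum(a) / sum(a+b+c); loci
    undefined in either population are excluded and counted. Negative
    estimates are reported as computed.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValidationError("each population needs >= 2 accessions")
    calls_a = matrix.calls[matrix.accession_index(pop_a), :]
    calls_b = matrix.calls[matrix.accession_index(pop_b), :]
    theta, a, b, c, usable = _theta_from_calls(calls_a, calls_b)
    if not usable.any():
        raise ValidationError(
            f"no shared informative locus between {labels[0]} and {labels[1]}"
        )
    return PairwiseDifferentiation(
        pop_a=labels[0], pop_b=labels[1], theta=theta,
        a_sum=float(a[usable].sum()), b_sum=float(b[usable].sum()),
        c_sum=float(c[usable].sum()),
        n_loci_used=int(usable.sum()), n_loci_excluded=int((~usable).sum()),
    )


# ---------------------------------------------------------------------------
# Nei's distance


def nei_distance(
    matrix: GenotypeMatrix, pop_a: Sequence[str], pop_b: Sequence[str]
) -> float:
    """Nei's (1978) standard genetic distance corrected for sample size.

    D = -ln(I), I = J_xy / sqrt(J_x J_y), with unbiased within-population
    identities J = (2n sum(p_i^2) - 1)/(2n - 1) averaged over loci. Returns
    ``inf`` (never raises) when I <= 0, e.g. under fixed differences at all
    loci.
    """
    sa = allele_frequencies(matrix, pop_a)
    sb = allele_frequencies(matrix, pop_b)
    shared = sa.defined & sb.defined & (sa.gene_copies >= 2) & (sb.gene_copies >= 2)
    if not shared.any():
        raise ValidationError("no shared locus with data in both populations")
    pa, pb = sa.p_alt[shared], sb.p_alt[shared]
    ca, cb = sa.gene_copies[shared].astype(float), sb.gene_copies[shared].astype(float)
    jxy = (pa * pb + (1 - pa) * (1 - pb)).mean()
    jx = ((ca * (pa**2 + (1 - pa) ** 2) - 1) / (ca - 1)).mean()
    jy = ((cb * (pb**2 + (1 - pb) ** 2) - 1) / (cb - 1)).mean()
    if jx <= 0 or jy <= 0:
        return float("inf")
    identity = jxy / np.sqrt(jx * jy)
    if identity <= 0:
        return float("inf")
    return float(-np.log(identity))


# ---------------------------------------------------------------------------
# permutation testing


def fst_permutation_test(
    matrix: GenotypeMatrix,
    population_map: PopulationMap,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[PairwiseDifferentiation]:
    """Pairwise theta + Nei's D for every population pair, with permutation p-values.

    The permutation unit is the accession: its full multilocus genotype moves
    with its label, preserving within-individual structure. p = (1 + #{theta_perm
    >= theta_obs}) / (1 + P), so p is never zero. Bonferroni flags use
    alpha / n_pairs. Accessions mapped to "unknown" are excluded up front.
    """
    pops = population_map.known_populations()
    members = {
        p: [a for a in matrix.accession_ids
            if a in population_map and population_map.population(a) == p]
        for p in pops
    }
    pops = [p for p in pops if len(members[p]) >= 2]
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    n_pairs = len(pairs)
    rng = np.random.default_rng(seed)
    results: list[PairwiseDifferentiation] = []
    for pa, pb in pairs:
        res = pairwise_fst(matrix, members[pa], members[pb], labels=(pa, pb))
        res.nei_D = nei_distance(matrix, members[pa], members[pb])
        if n_permutations >= 1:
            idx = matrix.accession_index(members[pa] + members[pb])
            pooled = matrix.calls[idx, :]
            n_a = len(members[pa])
            exceed = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled.shape[0])
                t, *_ = _theta_from_calls(pooled[perm[:n_a], :], pooled[perm[n_a:], :])
                if not np.isnan(t) and t >= res.theta:
                    exceed += 1
            res.p_value = (1 + exceed) / (1 + n_permutations)
            res.bonferroni_significant = res.p_value <= alpha / n_pairs
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# diversity summaries


@dataclass
class DiversityStats:
    population: str
    sample_size: int
    allelic_richness: float
    he: float
    pic: float
    rarefaction_size: int


def _population_members(matrix: GenotypeMatrix, popmap: PopulationMap) -> dict[str, list[str]]:
    return {
        p: [a for a in matrix.accession_ids
            if a in popmap and popmap.population(a) == p]
        for p in popmap.known_populations()
    }


def diversity_summary(
    matrix: GenotypeMatrix,
    population_map: PopulationMap,
    rarefaction_size: int | None = None,
    polymorphic_only_pic: bool = False,
) -> list[DiversityStats]:
    """Per-population allelic richness, mean He and mean PIC, plus an overall row.

    Accessions assigned to "unknown" are excluded throughout. Allelic richness
    uses a common rarefaction size across populations — by default the minimum
    called gene-copy count over (marker, population), floored at 2. PIC is
    averaged over all markers (monomorphic markers contribute 0) unless
    ``polymorphic_only_pic`` restricts to within-population polymorphic markers.
    """
    members = _population_members(matrix, population_map)
    members = {p: m for p, m in members.items() if len(m) > 0}
    if not members:
        raise ValidationError("no non-unknown population with members")
    spectra = {p: allele_frequencies(matrix, m) for p, m in members.items()}
    all_known = [a for m in members.values() for a in m]
    spectra["Total"] = allele_frequencies(matrix, all_known)
    sizes = {p: len(m) for p, m in members.items()}
    sizes["Total"] = len(all_known)

    if rarefaction_size is None:
        copy_mins = [s.gene_copies[s.gene_copies > 0].min() for s in spectra.values()]
        rarefaction_size = int(max(2, min(copy_mins)))
    g = rarefaction_size

    out: list[DiversityStats] = []
    for pop, spec in spectra.items():
        ok = spec.gene_copies >= max(g, 2)
        p = spec.p_alt[ok]
        copies = spec.gene_copies[ok].astype(float)
        counts = np.column_stack([np.round((1 - p) * copies), np.round(p * copies)])
        A = float(np.mean(allelic_richness(counts, g)))
        he = float(np.nanmean(expected_het_unbiased(p, copies / 2)))
        pic_vals = pic_biallelic(p)
        if polymorphic_only_pic:
            poly = (p > 0) & (p < 1)
            pic_mean = float(pic_vals[poly].mean()) if poly.any() else 0.0
        else:
            pic_mean = float(pic_vals.mean())
        out.append(DiversityStats(pop, sizes[pop], A, he, pic_mean, g))
    return out


def diversity_table(stats: list[DiversityStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": s.population,
                "sample_size": s.sample_size,
                "A": s.allelic_richness,
                "He": s.he,
                "PIC": s.pic,
            }
            for s in stats
        ]
    )


def differentiation_table(results: list[PairwiseDifferentiation]) -> pd.DataFrame:
    """Square matrix: Nei's D upper triangle, theta (with stars) lower triangle."""
    pops: list[str] = []
    for r in results:
        for p in (r.pop_a, r.pop_b):
            if p not in pops:
                pops.append(p)
    df = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for r in results:
        star = "*" if r.bonferroni_significant else ""
        df.loc[r.pop_b, r.pop_a] = f"{r.theta:.2f}{star}"
        df.loc[r.pop_a, r.pop_b] = "inf" if np.isinf(r.nei_D) else f"{r.nei_D:.2f}"
    return df
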