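"""Synthetic germplasm collections with known truth for parameter recovery.

Populations diverge from a shared ancestral allele-frequency pool under the
Balding-Nichols model: ancestral frequency p ~ Uniform(0.05, 0.95) per
marker, population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) where F is the
population's divergence from the ancestor (F = 0 means no divergence).
Accessions are either inbred lines (fully homozygous, allele drawn once per
marker), intraspecific F1s (cross of two distinct inbred lines from one
population's line pool), or interspecific F1s (cross of lines from two named
populations, labelled as their own hybrid population). Markers are placed
uniformly at random on the chromosomes and are unlinked. Genotyping noise —
per-cell missingness, whole-sample call-rate failures, and symmetric
dosage-flip errors — is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    MarkerRecord,
    PopulationMap,
    ValidationError,
)

_NUCS = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    name: str
    divergence: float          # Balding-Nichols F; 0 = undiverged
    n_inbred: int = 0
    n_intraspecific_f1: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0):
            raise ValidationError(f"divergence F={self.divergence} outside [0, 1)")
        if self.n_inbred < 0 or self.n_intraspecific_f1 < 0:
            raise ValidationError("accession counts must be >= 0")


@dataclass
class InterspecificSpec:
    pop_a: str
    pop_b: str
    count: int
    label: str | None = None


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    interspecific: list[InterspecificSpec] = field(default_factory=list)
    n_markers: int = 224
    n_chromosomes: int = 20
    chromosome_length_bp: int = 5_000_000
    missing_rate: float = 0.0
    sample_failure_rate: float = 0.0
    sample_failure_missing_rate: float = 0.8
    genotype_error_rate: float = 0.0
    residual_het: float = 0.0   # inbred residual heterozygosity; 0 = infinite selfing
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "sample_failure_rate",
                     "sample_failure_missing_rate", "genotype_error_rate",
                     "residual_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        names = {p.name for p in self.populations}
        for x in self.interspecific:
            if x.pop_a not in names or x.pop_b not in names:
                raise ValidationError(
                    f"interspecific pair references undefined population "
                    f"({x.pop_a!r}, {x.pop_b!r})"
                )


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    ancestral_freq: np.ndarray                   # per marker
    population_freq: dict[str, np.ndarray]      # per population per marker
    true_population: dict[str, str]
    parents: dict[str, tuple[str, str]]         # F1 accession -> line ids
    line_genotypes: dict[str, np.ndarray]       # haploid 0/1 per marker per line


def _population_frequencies(
    p_anc: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    if F == 0.0:
        return p_anc.copy()
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    return rng.beta(a, b)


def simulate_collection(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[MarkerRecord], PopulationMap, TruthRecord]:
    """Simulate one germplasm collection; same seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    # marker placement and alleles
    chroms = rng.integers(0, config.n_chromosomes, size=m)
    pos = rng.integers(1, config.chromosome_length_bp + 1, size=m)
    order = np.lexsort((pos, chroms))
    chroms, pos = chroms[order], pos[order]
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    markers = [
        MarkerRecord(
            marker_id=f"S{chroms[j] + 1}_{pos[j]}_{j}",
            chromosome=f"chr{chroms[j] + 1:02d}",
            position=int(pos[j]),
            ref_allele=str(_NUCS[ref_idx[j]]),
            alt_allele=str(_NUCS[alt_idx[j]]),
        )
        for j in range(m)
    ]

    p_anc = rng.uniform(0.05, 0.95, size=m)
    pop_freq = {
        p.name: _population_frequencies(p_anc, p.divergence, rng)
        for p in config.populations
    }

    # inbred line pools: each line is a haploid 0/1 vector (fully homozygous)
    line_genotypes: dict[str, np.ndarray] = {}
    line_pool: dict[str, list[str]] = {}
    for p in config.populations:
        n_f1 = p.n_intraspecific_f1
        needs_cross = n_f1 > 0 or any(
            x.count > 0 and p.name in (x.pop_a, x.pop_b) for x in config.interspecific
        )
        # enough lines for the named inbred accessions plus a crossing pool
        n_lines = p.n_inbred + (max(2, n_f1) if needs_cross else 0)
        pool = []
        for i in range(n_lines):
            lid = f"{p.name}_line{i:03d}"
            line_genotypes[lid] = (rng.random(m) < pop_freq[p.name]).astype(np.int8)
            pool.append(lid)
        line_pool[p.name] = pool

    accession_ids: list[str] = []
    rows: list[np.ndarray] = []
    assignments: dict[str, tuple[str, str]] = {}
    true_population: dict[str, str] = {}
    parents: dict[str, tuple[str, str]] = {}

    def _dose(hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
        return (hap_a + hap_b).astype(np.int8)

    for p in config.populations:
        pool = line_pool[p.name]
        for i in range(p.n_inbred):
            acc = f"{p.name}_inb{i:03d}"
            line = pool[i]
            geno = _dose(line_genotypes[line], line_genotypes[line])
            if config.residual_het > 0:
                flip = rng.random(m) < config.residual_het
                geno = np.where(flip, HET, geno).astype(np.int8)
            accession_ids.append(acc)
            rows.append(geno)
            atype = "breeding_line" if i % 2 == 0 else "landrace"
            assignments[acc] = (p.name, atype)
            true_population[acc] = p.name
            parents[acc] = (line, line)
        for i in range(p.n_intraspecific_f1):
            acc = f"{p.name}_f1_{i:03d}"
            pa, pb = rng.choice(len(pool), size=2, replace=False)
            la, lb = pool[pa], pool[pb]
            geno = _dose(line_genotypes[la], line_genotypes[lb])
            accession_ids.append(acc)
            rows.append(geno)
            assignments[acc] = (p.name, "F1")
            true_population[acc] = p.name
            parents[acc] = (la, lb)

    for x in config.interspecific:
        label = x.label or f"{x.pop_a}_x_{x.pop_b}"
        pool_a, pool_b = line_pool[x.pop_a], line_pool[x.pop_b]
        for i in range(x.count):
            acc = f"{label}_f1_{i:03d}"
            la = pool_a[rng.integers(0, len(pool_a))]
            lb = pool_b[rng.integers(0, len(pool_b))]
            geno = _dose(line_genotypes[la], line_genotypes[lb])
            accession_ids.append(acc)
            rows.append(geno)
            assignments[acc] = (label, "F1")
            true_population[acc] = label
            parents[acc] = (la, lb)

    calls = np.array(rows, dtype=np.int8)
    n = calls.shape[0]

    # genotyping noise, applied last
    if config.genotype_error_rate > 0:
        err = rng.random(calls.shape) < config.genotype_error_rate
        shift = np.where(calls == HOM_REF, 1, np.where(calls == HOM_ALT, -1, 0))
        het_dir = rng.integers(0, 2, size=calls.shape) * 2 - 1  # het flips either way
        shift = np.where(calls == HET, het_dir, shift)
        calls = np.where(err, calls + shift, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    if config.sample_failure_rate > 0:
        failed = rng.random(n) < config.sample_failure_rate
        extra = rng.random(calls.shape) < config.sample_failure_missing_rate
        calls[failed[:, None] & extra] = MISSING

    matrix = GenotypeMatrix(accession_ids, [mk.marker_id for mk in markers], calls)
    labels = {p.name for p in config.populations} | {
        x.label or f"{x.pop_a}_x_{x.pop_b}" for x in config.interspecific
    }
    popmap = PopulationMap(assignments, frozenset(labels))
    truth = TruthRecord(p_anc, pop_freq, true_population, parents, line_genotypes)
    return matrix, markers, popmap, truth


def pumpkin_preset(seed: int = 0) -> SimulationConfig:
    """Four-population pumpkin-collection preset: 73/63/45/31 accessions.

    Three species populations (maxima-like, moschata-like, pepo-like) mix
    inbred accessions with intraspecific F1 cultivars; the fourth population
    is 31 interspecific F1s crossed from the first two species' line pools.
    Divergence values are fixed so the two crossing species are the most
    strongly differentiated pair. 224 markers on 20 chromosomes.
    """
    return SimulationConfig(
        populations=[
            PopulationSpec("maxima", divergence=0.50, n_inbred=33, n_intraspecific_f1=40),
            PopulationSpec("moschata", divergence=0.50, n_inbred=28, n_intraspecific_f1=35),
            PopulationSpec("pepo", divergence=0.35, n_inbred=24, n_intraspecific_f1=21),
        ],
        interspecific=[InterspecificSpec("maxima", "moschata", count=31, label="maxima_x_moschata")],
        n_markers=224,
        n_chromosomes=20,
        chromosome_length_bp=15_000_000,
        missing_rate=0.02,
        genotype_error_rate=0.005,
        seed=seed,
    )
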