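"""Shared data model: genotype matrix, marker metadata, population map.

Genotype calls are ref/alt-relative integer codes rather than nucleotide
strings; every downstream statistic needs only allele counts, and nucleotide
rendering is a dialect concern of the table reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# call codes (int8)
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

CALL_STATES = (HOM_REF, HET, HOM_ALT, MISSING)

NUCLEOTIDES = frozenset("ACGT")

ACCESSION_TYPES = ("F1", "breeding_line", "landrace", "unknown")


class ValidationError(ValueError):
    """Raised when an input violates the data-model contracts."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Accessions x markers diploid calls with missing entries.

    ``calls`` is an int8 array of shape (n_accessions, n_markers) holding
    HOM_REF/HET/HOM_ALT/MISSING codes.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.marker_ids = list(self.marker_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.marker_ids, "marker")
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.calls, CALL_STATES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call code {self.calls[i, j]} at accession "
                f"{self.accession_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def accession_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown accession id {e.args[0]!r}") from None

    def marker_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown marker id {e.args[0]!r}") from None

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_index(ids)
        return GenotypeMatrix(list(ids), self.marker_ids, self.calls[idx, :])

    def subset_markers(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.marker_index(ids)
        return GenotypeMatrix(self.accession_ids, list(ids), self.calls[:, idx])

    def call_rates(self) -> np.ndarray:
        """Per-accession fraction of non-missing calls."""
        if self.n_markers == 0:
            return np.ones(self.n_accessions)
        return (self.calls != MISSING).mean(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class MarkerRecord:
    """One SNP marker: map position, alleles, optional annotation and QC stats."""

    marker_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    annotation_class: str | None = None
    pic: float | None = None
    maf: float | None = None
    missing_rate: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"marker {self.marker_id!r}: position must be 1-based >= 1, got {self.position}"
            )
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"marker {self.marker_id!r}: {name} allele {allele!r} is not one of A/C/G/T"
                )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"marker {self.marker_id!r}: ref == alt ({self.ref_allele})")
        for name, v in (("pic", self.pic), ("maf", self.maf), ("missing_rate", self.missing_rate)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"marker {self.marker_id!r}: {name}={v} outside [0, 1]")


@dataclass
class PopulationMap:
    """Accession -> (predefined population, accession type).

    ``populations`` is the declared label set; "unknown" is always allowed.
    """

    assignments: dict[str, tuple[str, str]]
    populations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.populations = frozenset(self.populations) | {"unknown"}
        for acc, (pop, atype) in self.assignments.items():
            if pop not in self.populations:
                raise ValidationError(
                    f"accession {acc!r}: population {pop!r} not in declared set "
                    f"{sorted(self.populations)}"
                )
            if atype not in ACCESSION_TYPES:
                raise ValidationError(
                    f"accession {acc!r}: unknown accession_type token {atype!r} "
                    f"(expected one of {ACCESSION_TYPES})"
                )

    def population(self, accession_id: str) -> str:
        return self.assignments[accession_id][0]

    def accession_type(self, accession_id: str) -> str:
        return self.assignments[accession_id][1]

    def accessions_in(self, population: str) -> list[str]:
        return [a for a, (p, _) in self.assignments.items() if p == population]

    def known_populations(self) -> list[str]:
        """Populations with at least one assigned accession, excluding 'unknown'."""
        seen: list[str] = []
        for _, (p, _) in self.assignments.items():
            if p != "unknown" and p not in seen:
                seen.append(p)
        return seen

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, accession_id: str) -> bool:
        return accession_id in self.assignments


def validate_population_map(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> dict[str, list[str]]:
    """Cross-validate a population map against a genotype matrix.

    Returns {"unassigned": accessions in the matrix without an assignment,
    "orphans": assigned accessions absent from the matrix}. Nothing is dropped.
    """
    matrix_set = set(matrix.accession_ids)
    assigned = set(popmap.assignments)
    return {
        "unassigned": [a for a in matrix.accession_ids if a not in assigned],
        "orphans": sorted(assigned - matrix_set),
    }
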