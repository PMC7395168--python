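"""Readers/writers for VCF, delimited genotype tables and population files.

The genotype-table reader is dialect-driven: supplementary tables from
different genotyping platforms render the same diploid call as "AA"/"AG"/"GG",
"0"/"1"/"2" or "XX"/"XY"/"YY", so the symbol set is declared per table rather
than hard-coded.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

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

logger = logging.getLogger(__name__)

DEFAULT_MISSING_SYMBOLS = ("./.", ".", "--", "NA", "")


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending location."""


# ---------------------------------------------------------------------------
# dialects


@dataclass
class Dialect:
    """Uniform symbol dialect: one symbol per call state for every marker."""

    hom_ref: str = "0"
    het: str = "1"
    hom_alt: str = "2"
    missing: tuple[str, ...] = DEFAULT_MISSING_SYMBOLS

    def decode(self, symbol: str, marker_id: str) -> int:
        s = symbol.strip()
        if s in self.missing:
            return MISSING
        if s == self.hom_ref:
            return HOM_REF
        if s == self.het:
            return HET
        if s == self.hom_alt:
            return HOM_ALT
        raise KeyError(s)

    def encode(self, call: int, marker_id: str) -> str:
        return {
            MISSING: self.missing[0],
            HOM_REF: self.hom_ref,
            HET: self.het,
            HOM_ALT: self.hom_alt,
        }[call]


@dataclass
class AllelePairDialect:
    """Allele-pair dialect ("AA"/"AG"/"GG"): symbols depend on marker alleles.

    Heterozygotes are accepted in either order (``AG`` == ``GA``).
    """

    markers: Mapping[str, MarkerRecord]
    missing: tuple[str, ...] = DEFAULT_MISSING_SYMBOLS

    def decode(self, symbol: str, marker_id: str) -> int:
        s = symbol.strip().upper()
        if s in (m.upper() for m in self.missing) or s == "":
            return MISSING
        rec = self.markers[marker_id]
        r, a = rec.ref_allele, rec.alt_allele
        if s == r + r:
            return HOM_REF
        if s == a + a:
            return HOM_ALT
        if s in (r + a, a + r):
            return HET
        raise KeyError(s)

    def encode(self, call: int, marker_id: str) -> str:
        rec = self.markers[marker_id]
        r, a = rec.ref_allele, rec.alt_allele
        return {MISSING: self.missing[0], HOM_REF: r + r, HET: r + a, HOM_ALT: a + a}[call]


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, list[MarkerRecord]]:
    """Read bi-allelic SNP records from a VCF into the shared data model.

    Non-SNP and multi-allelic records are dropped (counted and logged).
    Coordinates stay 1-based; marker order follows file order. Diploid GT is
    mapped to the four call states; "./." becomes missing. Haploid or
    polyploid GT entries raise :class:`ParseError`.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as e:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ParseError(f"cannot open VCF {path!r}: {e}") from e
    accession_ids = list(vcf.samples)
    markers: list[MarkerRecord] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_dropped += 1
            logger.info(
                "dropping non-biallelic-SNP record at %s:%d (%s -> %s)",
                variant.CHROM, variant.POS, variant.REF, ",".join(variant.ALT) or ".",
            )
            continue
        ploidies = {len(g) - 1 for g in variant.genotypes}  # last item is phase flag
        if ploidies != {2}:
            raise ParseError(
                f"non-diploid GT at {variant.CHROM}:{variant.POS} "
                f"(ploidy {sorted(ploidies)})"
            )
        # gts012: 0/1/2 = dosage, 3 = unknown
        codes = variant.gt_types.astype(np.int8)
        codes[codes == 3] = MISSING
        rows.append(codes)
        marker_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        markers.append(
            MarkerRecord(
                marker_id=marker_id,
                chromosome=variant.CHROM,
                position=variant.POS,
                ref_allele=variant.REF,
                alt_allele=variant.ALT[0],
            )
        )
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(accession_ids), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(accession_ids, [m.marker_id for m in markers], calls)
    return matrix, markers


def write_vcf(
    path: str | Path, matrix: GenotypeMatrix, markers: Sequence[MarkerRecord]
) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns."""
    if [m.marker_id for m in markers] != matrix.marker_ids:
        raise ValidationError("marker records do not match matrix marker ids")
    gt_strings = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(m.chromosome for m in markers):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accession_ids)
            + "\n"
        )
        for j, m in enumerate(markers):
            gts = "\t".join(gt_strings[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{m.chromosome}\t{m.position}\t{m.marker_id}\t{m.ref_allele}\t"
                f"{m.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# genotype tables


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_genotype_table(
    path: str | Path, dialect: Dialect | AllelePairDialect, delimiter: str | None = None
) -> GenotypeMatrix:
    """Read a delimited accession x marker genotype table.

    First column holds accession ids; the header row holds marker ids.
    Symbols outside the dialect raise :class:`ParseError` listing every
    offending (row, column) cell.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        marker_ids = [h.strip() for h in header[1:]]
        accession_ids: list[str] = []
        rows: list[list[int]] = []
        bad_cells: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, expected {len(header)})"
                )
            acc = row[0].strip()
            if acc in accession_ids:
                raise ParseError(f"{path}:{lineno}: duplicate accession id {acc!r}")
            accession_ids.append(acc)
            calls = []
            for m_id, cell in zip(marker_ids, row[1:]):
                try:
                    calls.append(dialect.decode(cell, m_id))
                except KeyError:
                    bad_cells.append(f"row {acc!r}, column {m_id!r}: symbol {cell.strip()!r}")
                    calls.append(MISSING)
            rows.append(calls)
        if bad_cells:
            raise ParseError(
                f"{path}: {len(bad_cells)} cell(s) outside dialect: " + "; ".join(bad_cells)
            )
    calls_arr = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(marker_ids)), dtype=np.int8)
    )
    return GenotypeMatrix(accession_ids, marker_ids, calls_arr)


def write_genotype_table(
    path: str | Path,
    matrix: GenotypeMatrix,
    dialect: Dialect | AllelePairDialect,
    delimiter: str | None = None,
) -> None:
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["accession_id", *matrix.marker_ids])
        for i, acc in enumerate(matrix.accession_ids):
            writer.writerow(
                [acc]
                + [
                    dialect.encode(int(c), m)
                    for m, c in zip(matrix.marker_ids, matrix.calls[i, :])
                ]
            )


# ---------------------------------------------------------------------------
# marker metadata and population files


def read_marker_table(path: str | Path, delimiter: str | None = None) -> list[MarkerRecord]:
    """Read marker metadata TSV/CSV: marker_id, chromosome, position, ref, alt[, annotation_class]."""
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    MarkerRecord(
                        marker_id=row["marker_id"].strip(),
                        chromosome=row["chromosome"].strip(),
                        position=int(row["position"]),
                        ref_allele=row["ref_allele"].strip().upper(),
                        alt_allele=row["alt_allele"].strip().upper(),
                        annotation_class=(row.get("annotation_class") or "").strip() or None,
                    )
                )
            except (KeyError, ValueError, ValidationError) as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return records


def write_marker_table(path: str | Path, markers: Sequence[MarkerRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["marker_id", "chromosome", "position", "ref_allele", "alt_allele",
             "annotation_class", "pic", "maf", "missing_rate"]
        )
        for m in markers:
            writer.writerow(
                [m.marker_id, m.chromosome, m.position, m.ref_allele, m.alt_allele,
                 m.annotation_class or "",
                 "" if m.pic is None else f"{m.pic:.6g}",
                 "" if m.maf is None else f"{m.maf:.6g}",
                 "" if m.missing_rate is None else f"{m.missing_rate:.6g}"]
            )


def read_population_file(
    path: str | Path,
    populations: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> PopulationMap:
    """Read accession_id / population / accession_type assignments.

    When ``populations`` is given it is the declared label set; otherwise the
    labels found in the file define it. Unmatched accessions relative to a
    matrix are reported by :func:`pumpkinpop.datamodel.validate_population_map`,
    never dropped here.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    assignments: dict[str, tuple[str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: empty file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            acc, pop, atype = (c.strip() for c in row[:3])
            if acc in assignments:
                raise ParseError(f"{path}:{lineno}: duplicate accession id {acc!r}")
            assignments[acc] = (pop, atype)
    declared = frozenset(populations) if populations is not None else frozenset(
        p for p, _ in assignments.values()
    )
    try:
        return PopulationMap(assignments, declared)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_population_file(path: str | Path, popmap: PopulationMap) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["accession_id", "population", "accession_type"])
        for acc, (pop, atype) in popmap.assignments.items():
            writer.writerow([acc, pop, atype])
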