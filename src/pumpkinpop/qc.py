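"""Marker- and sample-level quality control and substitution-type accounting.

Marker filters follow the array-genotyping convention of *strict* thresholds:
keep a marker iff MAF > maf_min and missing rate < missing_max. Flags allow
the inclusive variants. MAF is computed over gene copies: a heterozygote
contributes one copy of each allele and missing calls contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, ValidationError

TRANSITION_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})
# canonical Table-2-style subtype labels
_SUBTYPE_ORDER = ("A/G", "C/T", "A/T", "A/C", "G/T", "C/G")


@dataclass
class FilterCriteria:
    """Marker/sample filter thresholds; defaults mirror common array QC."""

    maf_min: float = 0.05
    missing_max: float = 0.10
    biallelic_only: bool = True
    sample_call_rate_min: float = 0.90
    # strict (exclusive) comparisons by default; set False for >= / <=
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")


def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, missing rate, observed het rate and called count.

    Markers with zero called genotypes get NaN maf/het_rate and are flagged
    via ``n_called == 0`` — never silently reported as maf 0.
    """
    if matrix.n_markers == 0 or matrix.n_accessions == 0:
        raise ValidationError("marker_stats requires a non-empty matrix")
    calls = matrix.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_alt_copies = (calls == HOM_ALT).sum(axis=0) * 2 + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, n_alt_copies / (2 * n_called), np.nan)
        het_rate = np.where(n_called > 0, n_het / n_called, np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)
    missing_rate = 1 - n_called / matrix.n_accessions
    return pd.DataFrame(
        {
            "maf": maf,
            "missing_rate": missing_rate,
            "het_rate": het_rate,
            "n_called": n_called,
        },
        index=pd.Index(matrix.marker_ids, name="marker_id"),
    )


def filter_markers(
    matrix: GenotypeMatrix, criteria: FilterCriteria
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply MAF/missingness filters; returns (filtered matrix, pass/fail report).

    The report has one row per input marker with columns maf, missing_rate,
    het_rate, pass and fail_reason.
    """
    stats = marker_stats(matrix)
    maf = stats["maf"].to_numpy()
    miss = stats["missing_rate"].to_numpy()
    if criteria.strict:
        maf_ok = maf > criteria.maf_min
        miss_ok = miss < criteria.missing_max
    else:
        maf_ok = maf >= criteria.maf_min
        miss_ok = miss <= criteria.missing_max
    maf_ok = np.where(np.isnan(maf), False, maf_ok)
    keep = maf_ok & miss_ok

    reasons = np.full(matrix.n_markers, "", dtype=object)
    reasons[~miss_ok] = "missing_rate"
    reasons[~maf_ok] = "maf"
    reasons[(~maf_ok) & (~miss_ok)] = "maf;missing_rate"
    reasons[np.isnan(maf)] = "no_called_genotypes"

    report = stats.copy()
    report["pass"] = keep
    report["fail_reason"] = reasons
    kept_ids = [m for m, k in zip(matrix.marker_ids, keep) if k]
    return matrix.subset_markers(kept_ids), report


def filter_samples_by_call_rate(
    matrix: GenotypeMatrix, threshold: float = 0.65
) -> tuple[GenotypeMatrix, list[tuple[str, float]]]:
    """Exclude accessions whose call rate falls strictly below ``threshold``.

    The default 0.65 removes catastrophic assay failures while retaining
    accessions in the ~0.8+ band; 0.90 is the stricter preset. Returns the
    filtered matrix and the exclusion list sorted ascending by call rate.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold={threshold} outside [0, 1]")
    rates = matrix.call_rates()
    excluded = sorted(
        [(a, float(r)) for a, r in zip(matrix.accession_ids, rates) if r < threshold],
        key=lambda t: (t[1], t[0]),
    )
    kept = [a for a, r in zip(matrix.accession_ids, rates) if r >= threshold]
    return matrix.subset_accessions(kept), excluded


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify an unordered allele pair as transition/transversion.

    Returns (class, subtype) with the subtype canonicalized to one of
    A/G, C/T, A/T, A/C, G/T, C/G.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValidationError(f"alleles must be single nucleotides, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref}); not a substitution")
    pair = frozenset((ref, alt))
    subtype = next(s for s in _SUBTYPE_ORDER if frozenset(s.split("/")) == pair)
    klass = "transition" if pair in TRANSITION_PAIRS else "transversion"
    return klass, subtype


def substitution_summary(markers) -> pd.DataFrame:
    """Count markers per substitution class/subtype (Table-2-style accounting)."""
    rows = [classify_substitution(m.ref_allele, m.alt_allele) for m in markers]
    df = pd.DataFrame(rows, columns=["class", "subtype"])
    counts = (
        df.groupby(["class", "subtype"]).size().rename("n_markers").reset_index()
    )
    return counts.sort_values(
        ["class", "subtype"],
        key=lambda s: s.map({v: i for i, v in enumerate(
            ["transition", "transversion", *_SUBTYPE_ORDER])}),
    ).reset_index(drop=True)
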