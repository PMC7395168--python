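"""Core-marker panel selection and the variety-identification statistic.

Panels are built distribution-aware: after a PIC floor, marker slots are
allocated to chromosomes proportionally to chromosome length
(largest-remainder rounding), each chromosome is partitioned into equal-length
bins, and the most informative marker per bin is taken. Nested subsets rank
by PIC under a per-chromosome coverage constraint. The identification
(distinguishability) statistic declares two accessions distinct iff at least
one panel marker shows two non-missing, differing calls; accessions not
distinct from someone form indistinguishable groups (connected components,
since "not distinct" need not be transitive under missingness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datamodel import MISSING, GenotypeMatrix, MarkerRecord, ValidationError


@dataclass
class PanelSpec:
    """Selection parameters for the distributed core panel and its subsets."""

    pic_min: float = 0.3
    target_size: int = 400
    nested_sizes: tuple[int, ...] = (192, 96, 48, 24, 12)
    chromosome_lengths: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pic_min <= 1.0):
            raise ValidationError(f"pic_min={self.pic_min} outside [0, 1]")
        sizes = tuple(self.nested_sizes)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError(f"nested sizes must be strictly descending: {sizes}")
        if sizes and sizes[0] > self.target_size:
            raise ValidationError("largest nested size exceeds target size")


@dataclass
class PanelReport:
    """Ordered marker panel with per-chromosome layout and identification results."""

    marker_ids: list[str]
    per_chromosome: pd.DataFrame | None = None  # chromosome, n_markers, mean_interval_mb
    identification_rate: float | None = None
    n_identified: int | None = None
    n_total: int | None = None
    indistinguishable_groups: list[set[str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.marker_ids)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer slots proportionally to ``weights``."""
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def _per_chromosome_layout(
    markers: Sequence[MarkerRecord], chromosome_lengths: Mapping[str, float] | None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {"chromosome": [m.chromosome for m in markers],
         "position": [m.position for m in markers]}
    )
    rows = []
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = np.sort(grp["position"].to_numpy())
        mean_int = float(np.diff(pos).mean()) / 1e6 if len(pos) > 1 else float("nan")
        length = chromosome_lengths.get(chrom) if chromosome_lengths else pos.max()
        rows.append(
            {"chromosome": chrom, "n_markers": len(pos),
             "mean_interval_mb": mean_int, "length_bp": length}
        )
    return pd.DataFrame(rows)


def select_distributed_panel(
    markers: Sequence[MarkerRecord], spec: PanelSpec
) -> PanelReport:
    """Select a genome-distributed, high-PIC core panel.

    Markers with PIC >= pic_min are eligible (inclusive floor). Slots go to
    chromosomes by length via largest-remainder rounding; each chromosome is
    split into equal-length bins and the max-PIC marker per bin is picked
    (ties by position). Empty bins release their slots to the best unchosen
    markers on the same chromosome; slots a chromosome cannot fill are
    redistributed to the globally best unchosen eligible markers.
    """
    for m in markers:
        if m.pic is None:
            raise ValidationError(f"marker {m.marker_id!r} has no PIC value")
    eligible = [m for m in markers if m.pic >= spec.pic_min]
    if not eligible:
        raise ValidationError(f"no marker reaches pic_min={spec.pic_min}")
    if len(eligible) < spec.target_size:
        warnings.warn(
            f"only {len(eligible)} eligible markers for target {spec.target_size}; "
            "returning all eligible"
        )
        chosen = sorted(eligible, key=lambda m: (m.chromosome, m.position))
        return PanelReport(
            [m.marker_id for m in chosen],
            per_chromosome=_per_chromosome_layout(chosen, spec.chromosome_lengths),
        )

    by_chrom: dict[str, list[MarkerRecord]] = {}
    for m in eligible:
        by_chrom.setdefault(m.chromosome, []).append(m)
    chroms = list(by_chrom)
    lengths = np.array(
        [
            (spec.chromosome_lengths or {}).get(
                c, max(m.position for m in by_chrom[c])
            )
            for c in chroms
        ],
        dtype=float,
    )
    slots = _largest_remainder(lengths, spec.target_size)

    chosen: list[MarkerRecord] = []
    unfilled = 0
    leftovers: list[MarkerRecord] = []
    for chrom, n_slots, length in zip(chroms, slots, lengths):
        cmarkers = sorted(by_chrom[chrom], key=lambda m: m.position)
        n_slots = int(n_slots)
        if n_slots == 0:
            leftovers.extend(cmarkers)
            continue
        take = min(n_slots, len(cmarkers))
        edges = np.linspace(0, length, take + 1)
        edges[-1] = max(edges[-1], cmarkers[-1].position)  # last bin closed
        picked: list[MarkerRecord] = []
        pool = list(cmarkers)
        for b in range(take):
            lo, hi = edges[b], edges[b + 1]
            in_bin = [m for m in pool if lo < m.position <= hi or (b == 0 and m.position <= hi)]
            if not in_bin:
                continue
            best = max(in_bin, key=lambda m: (m.pic, -m.position))
            picked.append(best)
            pool.remove(best)
        # empty bins release slots to the chromosome's best unchosen markers
        while len(picked) < take and pool:
            best = max(pool, key=lambda m: (m.pic, -m.position))
            picked.append(best)
            pool.remove(best)
        unfilled += n_slots - len(picked)
        leftovers.extend(pool)
        chosen.extend(picked)
    # slots a chromosome could not fill go to the globally best leftovers
    leftovers.sort(key=lambda m: (-m.pic, m.chromosome, m.position))
    chosen.extend(leftovers[:unfilled])

    chosen.sort(key=lambda m: (m.chromosome, m.position))
    return PanelReport(
        [m.marker_id for m in chosen],
        per_chromosome=_per_chromosome_layout(chosen, spec.chromosome_lengths),
    )


def nest_subsets(
    panel_markers: Sequence[MarkerRecord], nested_sizes: Sequence[int]
) -> list[PanelReport]:
    """Nested high-PIC subsets of a parent panel with chromosome coverage.

    Each subset is contained in its predecessor. Within the parent, markers
    rank by PIC (ties by chromosome, position); a repair pass then ensures no
    chromosome is left empty while another holds two or more, where feasible.
    """
    parent = list(panel_markers)
    for m in parent:
        if m.pic is None:
            raise ValidationError(f"marker {m.marker_id!r} has no PIC value")
    reports: list[PanelReport] = []
    for size in nested_sizes:
        if size > len(parent):
            raise ValidationError(f"subset size {size} exceeds parent size {len(parent)}")
        ranked = sorted(parent, key=lambda m: (-m.pic, m.chromosome, m.position))
        selected = ranked[:size]
        rest = ranked[size:]
        # coverage repair: pull in the best marker of each uncovered chromosome,
        # evicting the worst marker from a chromosome holding >= 2
        parent_chroms = {m.chromosome for m in parent}
        while True:
            covered = {m.chromosome for m in selected}
            uncovered = [c for c in sorted(parent_chroms - covered)
                         if any(m.chromosome == c for m in rest)]
            counts: dict[str, int] = {}
            for m in selected:
                counts[m.chromosome] = counts.get(m.chromosome, 0) + 1
            donors = [m for m in selected if counts[m.chromosome] >= 2]
            if not uncovered or not donors:
                break
            incoming = max(
                (m for m in rest if m.chromosome == uncovered[0]),
                key=lambda m: (m.pic, m.chromosome, -m.position),
            )
            outgoing = min(donors, key=lambda m: (m.pic, m.chromosome, -m.position))
            selected.remove(outgoing)
            rest.remove(incoming)
            selected.append(incoming)
            rest.append(outgoing)
        selected.sort(key=lambda m: (m.chromosome, m.position))
        reports.append(PanelReport([m.marker_id for m in selected],
                                   per_chromosome=_per_chromosome_layout(selected, None)))
        parent = selected
    return reports


def _distinct_matrix(
    calls: np.ndarray, missing_policy: str
) -> np.ndarray:
    """Boolean (n, n) matrix: True where accession pair is distinct."""
    n = calls.shape[0]
    distinct = np.zeros((n, n), dtype=bool)
    miss = calls == MISSING
    for i in range(n):
        both_called = ~miss[i] & ~miss
        differ = (calls[i] != calls) & both_called
        row = differ.any(axis=1)
        if missing_policy == "strict":
            one_missing = miss[i] ^ miss
            row |= one_missing.any(axis=1)
        distinct[i] = row
    np.fill_diagonal(distinct, False)
    return distinct


def distinguishability(
    matrix: GenotypeMatrix,
    panel_markers: Sequence[str],
    missing_policy: str = "conservative",
) -> PanelReport:
    """Variety-identification statistic of a marker panel.

    Two accessions are distinct iff some panel marker shows two non-missing,
    differing calls (``conservative``); ``strict`` additionally treats
    missing-vs-called as a difference. An accession is identified iff it is
    distinct from every other accession. Indistinguishable groups are the
    connected components (size >= 2) of the "not distinct" relation.
    """
    if len(panel_markers) == 0:
        raise ValidationError("empty panel")
    if missing_policy not in ("conservative", "strict"):
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    sub = matrix.subset_markers(list(panel_markers))
    distinct = _distinct_matrix(sub.calls, missing_policy)
    n = sub.n_accessions
    identified = distinct.sum(axis=1) == n - 1
    not_distinct = ~distinct
    np.fill_diagonal(not_distinct, False)
    n_comp, comp = connected_components(csr_matrix(not_distinct), directed=False)
    groups = []
    for c in range(n_comp):
        member_idx = np.flatnonzero(comp == c)
        if len(member_idx) >= 2:
            groups.append({sub.accession_ids[i] for i in member_idx})
    return PanelReport(
        list(panel_markers),
        identification_rate=float(identified.sum() / n),
        n_identified=int(identified.sum()),
        n_total=n,
        indistinguishable_groups=groups,
    )


def greedy_discriminating_set(
    matrix: GenotypeMatrix,
    candidate_markers: Sequence[str],
    stop_rate: float,
    pic_by_marker: Mapping[str, float] | None = None,
    marker_meta: Mapping[str, MarkerRecord] | None = None,
) -> tuple[list[str], float]:
    """Smallest greedy panel reaching a target identification rate.

    Iteratively adds the marker resolving the most currently-unresolved
    accession pairs; ties break by PIC descending then (chromosome, position)
    when metadata is supplied, else by candidate order. Returns (ordered
    marker list, achieved identification rate); if the target is unreachable
    the full candidate list is returned with the achieved rate.
    """
    if not candidate_markers:
        raise ValidationError("candidate marker list is empty")
    if not (0.0 < stop_rate <= 1.0):
        raise ValidationError(f"stop_rate={stop_rate} outside (0, 1]")
    sub = matrix.subset_markers(list(candidate_markers))
    calls = sub.calls
    n = sub.n_accessions
    iu, ju = np.triu_indices(n, k=1)
    # per-pair per-marker resolution: both called and differing
    miss = calls == MISSING
    resolves = (
        (calls[iu] != calls[ju]) & ~miss[iu] & ~miss[ju]
    )  # (n_pairs, n_markers)

    order = np.arange(len(candidate_markers))
    if pic_by_marker is not None or marker_meta is not None:
        def key(j: int):
            m = candidate_markers[j]
            p = (pic_by_marker or {}).get(m)
            if p is None and marker_meta is not None:
                p = marker_meta[m].pic
            meta = (marker_meta or {}).get(m)
            return (-(p or 0.0), meta.chromosome if meta else "", meta.position if meta else 0)
        order = np.array(sorted(order, key=key))

    chosen: list[int] = []
    unresolved = np.ones(len(iu), dtype=bool)
    remaining = set(order.tolist())
    while remaining:
        rate = _rate_from_unresolved(unresolved, iu, ju, n)
        if rate >= stop_rate:
            break
        gains = {j: int(resolves[unresolved, j].sum()) for j in remaining}
        best_gain = max(gains.values())
        # first marker in tie-break order achieving the best gain
        best = next(j for j in order.tolist() if j in remaining and gains[j] == best_gain)
        if gains[best] == 0:
            break
        chosen.append(best)
        remaining.discard(best)
        unresolved &= ~resolves[:, best]
    rate = _rate_from_unresolved(unresolved, iu, ju, n)
    if rate < stop_rate and remaining:
        # target unreachable: return everything with the achieved rate
        chosen.extend(j for j in order.tolist() if j in remaining)
        unresolved_final = unresolved.copy()
        for j in chosen:
            unresolved_final &= ~resolves[:, j]
        rate = _rate_from_unresolved(unresolved_final, iu, ju, n)
    return [candidate_markers[j] for j in chosen], float(rate)


def _rate_from_unresolved(
    unresolved: np.ndarray, iu: np.ndarray, ju: np.ndarray, n: int
) -> float:
    in_unresolved = np.zeros(n, dtype=bool)
    in_unresolved[iu[unresolved]] = True
    in_unresolved[ju[unresolved]] = True
    return float((~in_unresolved).sum() / n)


def identification_report(report: PanelReport) -> pd.DataFrame:
    """Per-accession identification table for a computed PanelReport."""
    grouped: dict[str, int] = {}
    for gid, group in enumerate(report.indistinguishable_groups, start=1):
        for acc in group:
            grouped[acc] = gid
    rows = [
        {"accession_id": acc, "identified": acc not in grouped,
         "group_id": grouped.get(acc, "")}
        for acc in sorted(grouped)
    ]
    return pd.DataFrame(rows)
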