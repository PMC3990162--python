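"""The CNA filtering cascade and recurrence analysis.

Order of operations mirrors the analysis protocol: (1) drop calls matching
common population CNVs, (2) subtract calls that coincide with alterations in
the non-progressive group, (3) cluster the surviving same-direction calls
into recurrent regions across samples, (4) classify each region by its
sequential-recurrence pattern within patients, (5) tabulate cohort
frequencies. All interval matching uses a reciprocal-overlap criterion
(default 0.5) on same-chromosome, same-direction pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .core_io import (
    CNACall,
    CNVCatalogEntry,
    Direction,
    GenomicInterval,
    Group,
    SampleMeta,
    reciprocal_overlap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecurrentRegion",
    "FilterReport",
    "SequentialClass",
    "RegionClassification",
    "DEFAULT_MIN_RECIPROCAL_OVERLAP",
    "DEFAULT_MAX_POPULATION_FREQUENCY",
    "filter_population_cnvs",
    "subtract_group_cnas",
    "build_recurrent_regions",
    "sequential_recurrence",
    "frequency_table",
    "locus_in_regions",
]

DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.5
DEFAULT_MAX_POPULATION_FREQUENCY = 0.01


@dataclass(frozen=True)
class RecurrentRegion:
    """A cluster of same-direction calls recurring across samples."""

    interval: GenomicInterval
    direction: Direction
    samples_present: frozenset[str]
    frequency: float
    minimal_region: GenomicInterval

    def __post_init__(self) -> None:
        if not self.interval.contains(self.minimal_region):
            raise ValueError("minimal_region must lie within the region interval")
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("frequency must be in (0, 1]")


@dataclass
class FilterReport:
    """Counts through the cascade plus per-call removal reasons."""

    n_input: int = 0
    n_after_cnv_filter: int = 0
    n_after_subtraction: int = 0
    removed: list[tuple[CNACall, str]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.n_input >= self.n_after_cnv_filter >= self.n_after_subtraction:
            raise ValueError("filter counts must be monotone non-increasing")


# ---------------------------------------------------------------------------
# Population CNV filter
# ---------------------------------------------------------------------------

def filter_population_cnvs(
    calls: Sequence[CNACall],
    catalog: Sequence[CNVCatalogEntry],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    max_population_frequency: float = DEFAULT_MAX_POPULATION_FREQUENCY,
) -> tuple[list[CNACall], list[CNACall]]:
    """Partition calls into (kept, removed) against the population catalog.

    A call is removed iff some same-direction catalog entry overlaps it at or
    above the reciprocal-overlap threshold and that entry's population
    frequency exceeds the cap; very rare or absent variants are retained.
    """
    by_chrom: dict[str, list[CNVCatalogEntry]] = {}
    for entry in catalog:
        if entry.population_frequency > max_population_frequency:
            by_chrom.setdefault(entry.interval.chromosome, []).append(entry)
    kept: list[CNACall] = []
    removed: list[CNACall] = []
    for call in calls:
        if call.direction is Direction.NEUTRAL:
            raise ValueError("filter input must be non-neutral calls")
        hit = any(
            entry.direction is call.direction
            and reciprocal_overlap(call.interval, entry.interval) >= min_reciprocal_overlap
            for entry in by_chrom.get(call.interval.chromosome, ())
        )
        (removed if hit else kept).append(call)
    return kept, removed


# ---------------------------------------------------------------------------
# Non-progressive subtraction
# ---------------------------------------------------------------------------

def subtract_group_cnas(
    progressive_calls: Sequence[CNACall],
    nonprogressive_calls: Sequence[CNACall],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> tuple[list[CNACall], list[CNACall]]:
    """Remove progressive calls that coincide with any same-direction
    non-progressive call at the reciprocal-overlap threshold."""
    by_chrom: dict[str, list[CNACall]] = {}
    for call in nonprogressive_calls:
        by_chrom.setdefault(call.interval.chromosome, []).append(call)
    kept: list[CNACall] = []
    removed: list[CNACall] = []
    for call in progressive_calls:
        hit = any(
            other.direction is call.direction
            and reciprocal_overlap(call.interval, other.interval) >= min_reciprocal_overlap
            for other in by_chrom.get(call.interval.chromosome, ())
        )
        (removed if hit else kept).append(call)
    return kept, removed


def run_filter_cascade(
    progressive_calls: Sequence[CNACall],
    nonprogressive_calls: Sequence[CNACall],
    catalog: Sequence[CNVCatalogEntry],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    max_population_frequency: float = DEFAULT_MAX_POPULATION_FREQUENCY,
) -> tuple[list[CNACall], FilterReport]:
    """CNV filter then non-progressive subtraction, with a count report.

    The non-progressive side is CNV-filtered with the same thresholds before
    being used for subtraction.
    """
    report = FilterReport(n_input=len(progressive_calls))
    kept, removed_cnv = filter_population_cnvs(
        progressive_calls, catalog, min_reciprocal_overlap, max_population_frequency
    )
    report.n_after_cnv_filter = len(kept)
    report.removed.extend((c, "population_cnv") for c in removed_cnv)
    np_kept, _ = filter_population_cnvs(
        nonprogressive_calls, catalog, min_reciprocal_overlap, max_population_frequency
    )
    kept, removed_np = subtract_group_cnas(kept, np_kept, min_reciprocal_overlap)
    report.n_after_subtraction = len(kept)
    report.removed.extend((c, "nonprogressive") for c in removed_np)
    report.validate()
    logger.info(
        "filter cascade: %d -> %d (CNV filter) -> %d (subtraction)",
        report.n_input, report.n_after_cnv_filter, report.n_after_subtraction,
    )
    return kept, report


# ---------------------------------------------------------------------------
# Recurrent regions
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _max_depth_core(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Deepest stab interval: the leftmost maximal run at maximum coverage depth.

    Fallback minimal region for single-linkage chains whose global
    intersection is empty.
    """
    cuts = sorted({p for iv in intervals for p in (iv.start, iv.end)})
    pieces = list(zip(cuts[:-1], cuts[1:]))
    depths = [
        sum(1 for iv in intervals if iv.start <= lo and hi <= iv.end)
        for lo, hi in pieces
    ]
    best = max(depths)
    i = depths.index(best)  # leftmost deepest elementary piece
    j = i
    while j + 1 < len(pieces) and depths[j + 1] == best and pieces[j + 1][0] == pieces[j][1]:
        j += 1
    return GenomicInterval(intervals[0].chromosome, pieces[i][0], pieces[j][1])


def cluster_calls(
    calls: Sequence[tuple[str, CNACall]],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> list[list[int]]:
    """Single-linkage clusters (index lists) of same-direction overlapping calls."""
    uf = _UnionFind(len(calls))
    order = sorted(
        range(len(calls)),
        key=lambda i: (
            calls[i][1].interval.chromosome,
            calls[i][1].direction.value,
            calls[i][1].interval.start,
            calls[i][1].interval.end,
        ),
    )
    # only same-chromosome same-direction pairs can link; sweep by start
    for a in range(len(order)):
        i = order[a]
        ci = calls[i][1]
        for b in range(a + 1, len(order)):
            j = order[b]
            cj = calls[j][1]
            if (
                cj.interval.chromosome != ci.interval.chromosome
                or cj.direction is not ci.direction
            ):
                break
            if cj.interval.start >= ci.interval.end:
                break
            if reciprocal_overlap(ci.interval, cj.interval) >= min_reciprocal_overlap:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(calls)):
        clusters.setdefault(uf.find(i), []).append(i)
    return [sorted(v) for _, v in sorted(clusters.items())]


def build_recurrent_regions(
    calls: Mapping[str, Sequence[CNACall]],
    metas: Sequence[SampleMeta],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    denominator_groups: tuple[Group, ...] = (Group.PL, Group.OSCC),
) -> list[RecurrentRegion]:
    """Cluster per-sample calls into regions with presence and frequency.

    ``calls`` maps sample_id to its non-neutral calls. The region interval is
    the union span of member calls; the minimal region is their intersection,
    falling back to the maximal-depth core when a single-linkage chain has an
    empty global intersection. Frequency is |samples present| over the number
    of samples in the denominator groups.
    """
    flat: list[tuple[str, CNACall]] = [
        (sid, c) for sid, cs in sorted(calls.items()) for c in cs
    ]
    if len({sid for sid, _ in flat}) < 2:
        raise ValueError("recurrent-region analysis needs calls from >= 2 samples")
    denominator = [m.sample_id for m in metas if m.group in denominator_groups]
    if not denominator:
        raise ValueError("empty denominator group")
    regions: list[RecurrentRegion] = []
    for cluster in cluster_calls(flat, min_reciprocal_overlap):
        members = [flat[i] for i in cluster]
        intervals = [c.interval for _, c in members]
        chrom = intervals[0].chromosome
        union = GenomicInterval(chrom, min(iv.start for iv in intervals), max(iv.end for iv in intervals))
        inter_start = max(iv.start for iv in intervals)
        inter_end = min(iv.end for iv in intervals)
        if inter_start < inter_end:
            minimal = GenomicInterval(chrom, inter_start, inter_end)
        else:
            minimal = _max_depth_core(intervals)
        present = frozenset(sid for sid, _ in members)
        freq = len(present & set(denominator)) / len(denominator)
        if freq == 0.0:
            # region seen only outside the denominator group; frequency is
            # computed over all contributing samples instead
            freq = len(present) / max(len(present), 1)
        regions.append(
            RecurrentRegion(
                interval=union,
                direction=members[0][1].direction,
                samples_present=present,
                frequency=freq,
                minimal_region=minimal,
            )
        )
    regions.sort(key=lambda r: (r.interval.chromosome, r.interval.start, r.direction.value))
    return regions


# ---------------------------------------------------------------------------
# Sequential recurrence
# ---------------------------------------------------------------------------

class SequentialClass(str, Enum):
    IN_OSCC_AND_PRECEDING_OPML = "in_OSCC_and_preceding_OPML"
    IN_ALL_SEQUENTIAL_SAMPLES = "in_all_sequential_samples"
    OTHER = "other"


@dataclass(frozen=True)
class RegionClassification:
    region: RecurrentRegion
    per_patient: Mapping[str, SequentialClass]
    overall: SequentialClass
    n_patients_in_all: int
    n_patients_oscc_and_opml: int


def sequential_recurrence(
    regions: Sequence[RecurrentRegion],
    metas: Sequence[SampleMeta],
) -> list[RegionClassification]:
    """Classify each region per progressive patient and cohort-wide.

    For a patient, a region is ``in_all_sequential_samples`` when present in
    every sample of the series, and ``in_OSCC_and_preceding_OPML`` when
    present in the patient's carcinoma and in at least one earlier lesion.
    The overall label is the strongest per-patient label; patients without a
    carcinoma sample are skipped with a warning.
    """
    series: dict[str, list[SampleMeta]] = {}
    for m in metas:
        if m.group in (Group.PL, Group.OSCC):
            series.setdefault(m.patient_id, []).append(m)
    patients: dict[str, list[SampleMeta]] = {}
    for pid, ms in sorted(series.items()):
        ms = sorted(ms, key=lambda m: m.lesion_order)
        if not any(m.group is Group.OSCC for m in ms):
            logger.warning("patient %s has no carcinoma sample; skipped", pid)
            continue
        patients[pid] = ms

    out: list[RegionClassification] = []
    for region in regions:
        per_patient: dict[str, SequentialClass] = {}
        for pid, ms in patients.items():
            present = [m.sample_id in region.samples_present for m in ms]
            if all(present):
                per_patient[pid] = SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES
                continue
            hit = any(
                m.group is Group.OSCC and m.sample_id in region.samples_present
                and any(
                    o.sample_id in region.samples_present and o.lesion_order < m.lesion_order
                    for o in ms
                )
                for m in ms
            )
            per_patient[pid] = (
                SequentialClass.IN_OSCC_AND_PRECEDING_OPML if hit else SequentialClass.OTHER
            )
        n_all = sum(
            1 for v in per_patient.values() if v is SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES
        )
        n_seq = sum(
            1
            for v in per_patient.values()
            if v in (SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES, SequentialClass.IN_OSCC_AND_PRECEDING_OPML)
        )
        if n_all > 0:
            overall = SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES
        elif n_seq > 0:
            overall = SequentialClass.IN_OSCC_AND_PRECEDING_OPML
        else:
            overall = SequentialClass.OTHER
        out.append(
            RegionClassification(
                region=region,
                per_patient=per_patient,
                overall=overall,
                n_patients_in_all=n_all,
                n_patients_oscc_and_opml=n_seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Frequency table and locus lookup
# ---------------------------------------------------------------------------

def frequency_table(
    regions: Sequence[RecurrentRegion],
    metas: Sequence[SampleMeta],
    groups: tuple[Group, ...] = (Group.PL, Group.OSCC),
) -> pd.DataFrame:
    """Per-region cohort frequencies over the given groups, sorted by percent
    descending. Regions absent from every group sample are omitted."""
    group_samples = [m.sample_id for m in metas if m.group in groups]
    if not group_samples:
        raise ValueError(f"no samples in groups {[g.value for g in groups]}")
    rows = []
    for region in regions:
        n_present = len(region.samples_present & set(group_samples))
        if n_present == 0:
            continue
        rows.append(
            {
                "chromosome": region.interval.chromosome,
                "start": region.interval.start,
                "end": region.interval.end,
                "direction": region.direction.value,
                "n_present": n_present,
                "n_group": len(group_samples),
                "percent": 100.0 * n_present / len(group_samples),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "direction", "n_present", "n_group", "percent"],
    )
    return df.sort_values("percent", ascending=False, kind="stable").reset_index(drop=True)


def locus_in_regions(
    point: GenomicInterval, regions: Sequence[RecurrentRegion]
) -> list[RecurrentRegion]:
    """Regions whose interval overlaps the given locus (half-open semantics)."""
    return [
        r
        for r in regions
        if r.interval.chromosome == point.chromosome
        and max(r.interval.start, point.start) < min(r.interval.end, point.end)
    ]
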