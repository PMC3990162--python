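"""Domain types, genomic-interval arithmetic, and plain-text readers/writers.

Coordinates are 0-based half-open throughout (BED convention). Probes are
single points treated as length-1 intervals for overlap purposes. Only
autosomes (``chr1``..``chr22``) are admitted; sex-chromosome rows are dropped
at ingest with a logged count.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AUTOSOMES: frozenset[str] = frozenset(f"chr{i}" for i in range(1, 23))
SEX_CHROMOSOMES: frozenset[str] = frozenset({"chrX", "chrY", "chrM", "chrMT"})

__all__ = [
    "AUTOSOMES",
    "GenomicInterval",
    "ProbeProfile",
    "Segment",
    "CNACall",
    "Direction",
    "Group",
    "Grade",
    "Tobacco",
    "SampleMeta",
    "CNVCatalogEntry",
    "normalize_chromosome",
    "is_sex_chromosome",
    "reciprocal_overlap",
    "overlap_length",
    "read_probe_profile",
    "write_probe_profile",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_calls_bed",
    "write_calls_bed",
    "read_cnv_catalog",
    "write_cnv_catalog",
    "read_cytobands",
    "band_label",
    "parse_grade",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; message names the line."""


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to the canonical ``chr``-prefixed form."""
    label = label.strip()
    if not label.lower().startswith("chr"):
        label = "chr" + label
    return "chr" + label[3:]


def is_sex_chromosome(label: str) -> bool:
    return normalize_chromosome(label).upper() in {c.upper() for c in SEX_CHROMOSOMES}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on an autosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chromosome not in AUTOSOMES:
            raise ValueError(
                f"chromosome {self.chromosome!r} is not a recognized autosome "
                f"(chr1..chr22); sex chromosomes are excluded at ingest"
            )
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 if disjoint)."""
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 0 when chromosomes differ or disjoint."""
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


class ProbeProfile:
    """One sample's ordered (chromosome, position, log2 ratio) measurements.

    Stored as parallel arrays sorted by (chromosome, position); positions are
    strictly increasing within a chromosome and log2 ratios are finite.
    """

    __slots__ = ("sample_id", "chromosomes", "positions", "log2")

    def __init__(
        self,
        sample_id: str,
        chromosomes: Sequence[str],
        positions: Sequence[int],
        log2: Sequence[float],
    ) -> None:
        chroms = np.asarray(chromosomes, dtype=object)
        pos = np.asarray(positions, dtype=np.int64)
        vals = np.asarray(log2, dtype=np.float64)
        if not (len(chroms) == len(pos) == len(vals)):
            raise ValueError("chromosomes, positions and log2 must have equal length")
        if len(pos) == 0:
            raise ValueError("empty probe profile (zero autosomal probes)")
        for c in dict.fromkeys(chroms):
            if c not in AUTOSOMES:
                raise ValueError(f"non-autosomal chromosome {c!r} in profile")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite log2 ratio in profile")
        order = _sort_order(chroms, pos)
        chroms, pos, vals = chroms[order], pos[order], vals[order]
        for c, idx in _chromosome_slices(chroms).items():
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"duplicate or non-increasing positions on {c}")
        self.sample_id = sample_id
        self.chromosomes = chroms
        self.positions = pos
        self.log2 = vals

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.log2, other.log2)
        )

    def chromosome_order(self) -> list[str]:
        return list(dict.fromkeys(self.chromosomes))

    def by_chromosome(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Mapping chromosome -> (positions, log2) views, in profile order."""
        return {
            c: (self.positions[sl], self.log2[sl])
            for c, sl in _chromosome_slices(self.chromosomes).items()
        }

    def same_grid(self, other: "ProbeProfile") -> bool:
        return np.array_equal(self.chromosomes, other.chromosomes) and np.array_equal(
            self.positions, other.positions
        )


def _sort_order(chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
    # chromosome labels sort numerically (chr2 < chr10)
    ranks = np.array([int(str(c)[3:]) for c in chroms], dtype=np.int64)
    return np.lexsort((pos, ranks))


def _chromosome_slices(chroms: np.ndarray) -> dict[str, slice]:
    out: dict[str, slice] = {}
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out[chroms[start]] = slice(start, i)
            start = i
    return out


@dataclass(frozen=True)
class Segment:
    """Contiguous run of probes with its summary statistics."""

    interval: GenomicInterval
    mean_log2: float
    n_markers: int
    sd_log2: float

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("segment must contain at least one probe")
        if self.sd_log2 < 0:
            raise ValueError("negative sd_log2")


class Direction(str, Enum):
    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class CNACall:
    """A segment with a gain/loss/neutral status on the linear-ratio scale."""

    segment: Segment
    direction: Direction

    @property
    def linear_ratio(self) -> float:
        return float(2.0 ** self.segment.mean_log2)

    @property
    def interval(self) -> GenomicInterval:
        return self.segment.interval


class Group(str, Enum):
    PL = "PL"  # progressive leukoplakia
    NPL = "NPL"  # non-progressive leukoplakia
    OSCC = "OSCC"
    NORMAL = "NORMAL"


class Grade(str, Enum):
    NON_DYSPLASTIC = "non_dysplastic"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE_OR_CIS = "severe_or_CIS"
    CARCINOMA = "carcinoma"


GRADE_RANK: dict[Grade, int] = {g: i for i, g in enumerate(Grade)}


class Tobacco(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    group: Group
    grade: Grade
    lesion_order: int
    tobacco: Tobacco = Tobacco.UNKNOWN

    def __post_init__(self) -> None:
        if self.group is Group.OSCC and self.grade is not Grade.CARCINOMA:
            raise ValueError(
                f"sample {self.sample_id}: OSCC samples must carry grade carcinoma"
            )


@dataclass(frozen=True)
class CNVCatalogEntry:
    """Population copy-number-variant interval with direction and frequency."""

    interval: GenomicInterval
    direction: Direction
    population_frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.direction is Direction.NEUTRAL:
            raise ValueError("catalog entries are gain or loss, never neutral")
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError(
                f"population_frequency {self.population_frequency} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# Grade parsing
# ---------------------------------------------------------------------------

def parse_grade(label: str) -> Grade:
    """Map a histology label to a Grade; mixed labels take the higher grade.

    Severe dysplasia and carcinoma in situ share one level. Labels joined with
    '+' or '/' (e.g. "Moderate + Severe dysplasia") resolve to the highest
    component grade.
    """
    parts = [p.strip() for p in label.replace("/", "+").split("+") if p.strip()]
    if not parts:
        raise ValueError("empty grade label")
    grades = [_parse_single_grade(p) for p in parts]
    return max(grades, key=GRADE_RANK.__getitem__)


def _parse_single_grade(text: str) -> Grade:
    t = text.lower()
    try:
        return Grade(text)
    except ValueError:
        pass
    if "in situ" in t or "cis" == t.strip():
        return Grade.SEVERE_OR_CIS
    if "carcinoma" in t or "oscc" in t or "scc" in t:
        return Grade.CARCINOMA
    if "severe" in t:
        return Grade.SEVERE_OR_CIS
    if "moderate" in t:
        return Grade.MODERATE
    if "mild" in t:
        return Grade.MILD
    if any(w in t for w in ("keratosis", "hyperplasia", "non-dysplastic", "non_dysplastic", "normal")):
        return Grade.NON_DYSPLASTIC
    raise ValueError(f"unrecognized histology grade label: {text!r}")


# ---------------------------------------------------------------------------
# Probe TSV
# ---------------------------------------------------------------------------

_PROBE_COLUMNS = ("chromosome", "position", "log2_ratio")


def read_probe_profile(path: str | Path, sample_id: str) -> ProbeProfile:
    """Read a tab-separated probe table into a sorted :class:`ProbeProfile`.

    Expects header columns ``chromosome``, ``position``, ``log2_ratio``.
    Sex-chromosome rows are dropped (count logged); the result is sorted even
    if the file is not.
    """
    path = Path(path)
    chroms: list[str] = []
    positions: list[int] = []
    values: list[float] = []
    n_dropped = 0
    with path.open() as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = [c.strip() for c in header.rstrip("\n").split("\t")]
        try:
            idx = {name: cols.index(name) for name in _PROBE_COLUMNS}
        except ValueError as exc:
            raise ParseError(
                f"{path}: line 1: missing required columns {_PROBE_COLUMNS}"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                chrom = normalize_chromosome(fields[idx["chromosome"]])
                pos = int(fields[idx["position"]])
                val = float(fields[idx["log2_ratio"]])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed row: {line!r}") from exc
            if is_sex_chromosome(chrom):
                n_dropped += 1
                continue
            if chrom not in AUTOSOMES:
                raise ParseError(
                    f"{path}: line {lineno}: unrecognized chromosome {chrom!r}"
                )
            if not np.isfinite(val):
                raise ParseError(f"{path}: line {lineno}: non-finite log2 ratio")
            chroms.append(chrom)
            positions.append(pos)
            values.append(val)
    if n_dropped:
        logger.info("%s: dropped %d sex-chromosome probe(s)", path, n_dropped)
    if not chroms:
        raise ParseError(f"{path}: zero autosomal probes")
    return ProbeProfile(sample_id, chroms, positions, values)


def write_probe_profile(profile: ProbeProfile, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chromosome\tposition\tlog2_ratio\n")
        for c, p, v in zip(profile.chromosomes, profile.positions, profile.log2):
            fh.write(f"{c}\t{p}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Sample sheet CSV
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ("sample_id", "patient_id", "group", "grade", "lesion_order", "tobacco")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read and validate a sample sheet CSV into SampleMeta records."""
    path = Path(path)
    metas: list[SampleMeta] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_SHEET_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing sample sheet columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                meta = SampleMeta(
                    sample_id=sid,
                    patient_id=row["patient_id"].strip(),
                    group=Group(row["group"].strip()),
                    grade=parse_grade(row["grade"]),
                    lesion_order=int(row["lesion_order"]),
                    tobacco=Tobacco(row["tobacco"].strip().lower() or "unknown"),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            metas.append(meta)
    _check_unique_lesion_order(metas, path)
    return metas


def _check_unique_lesion_order(metas: Iterable[SampleMeta], path: Path) -> None:
    seen: set[tuple[str, int]] = set()
    for m in metas:
        key = (m.patient_id, m.lesion_order)
        if key in seen:
            raise ParseError(
                f"{path}: duplicate lesion_order {m.lesion_order} for patient {m.patient_id}"
            )
        seen.add(key)


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SHEET_COLUMNS)
        for m in metas:
            writer.writerow(
                [m.sample_id, m.patient_id, m.group.value, m.grade.value, m.lesion_order, m.tobacco.value]
            )


# ---------------------------------------------------------------------------
# Calls BED5+
# ---------------------------------------------------------------------------

def write_calls_bed(
    calls: Sequence[CNACall], path: str | Path, sample_id: str = "sample"
) -> None:
    """Write calls as BED5+ (chrom, start, end, name, score, direction,
    n_markers, sd_log2); score is mean_log2 x 1000, rounded."""
    with Path(path).open("w") as fh:
        for call in calls:
            iv = call.segment.interval
            score = round(call.segment.mean_log2 * 1000)
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t"
                f"{sample_id}:{call.direction.value}\t{score}\t"
                f"{call.direction.value}\t{call.segment.n_markers}\t"
                f"{call.segment.sd_log2:.6f}\n"
            )


def read_calls_bed(path: str | Path) -> list[tuple[str, CNACall]]:
    """Read a calls BED written by :func:`write_calls_bed`.

    Returns (sample_id, call) pairs; mean_log2 is recovered from the score
    column at 3-decimal precision.
    """
    out: list[tuple[str, CNACall]] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom = normalize_chromosome(fields[0])
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = int(fields[4])
                direction = Direction(fields[5])
                n_markers = int(fields[6])
                sd = float(fields[7]) if len(fields) > 7 else 0.0
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed BED row") from exc
            sample_id = name.rsplit(":", 1)[0]
            seg = Segment(
                interval=GenomicInterval(chrom, start, end),
                mean_log2=score / 1000.0,
                n_markers=n_markers,
                sd_log2=sd,
            )
            out.append((sample_id, CNACall(segment=seg, direction=direction)))
    return out


# ---------------------------------------------------------------------------
# CNV catalog BED4+
# ---------------------------------------------------------------------------

def read_cnv_catalog(path: str | Path) -> list[CNVCatalogEntry]:
    """Read a catalog BED4+ (chrom, start, end, direction[, frequency]).

    Entries without a frequency column are assumed common (frequency 1.0),
    i.e. removable by the population filter at any cap.
    """
    entries: list[CNVCatalogEntry] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom = normalize_chromosome(fields[0])
                if is_sex_chromosome(chrom):
                    continue
                entry = CNVCatalogEntry(
                    interval=GenomicInterval(chrom, int(fields[1]), int(fields[2])),
                    direction=Direction(fields[3]),
                    population_frequency=float(fields[4]) if len(fields) > 4 else 1.0,
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed catalog row") from exc
            entries.append(entry)
    return entries


def write_cnv_catalog(entries: Sequence[CNVCatalogEntry], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in entries:
            iv = e.interval
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{e.direction.value}\t"
                f"{e.population_frequency!r}\n"
            )


# ---------------------------------------------------------------------------
# Cytobands (optional display annotation)
# ---------------------------------------------------------------------------

def read_cytobands(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read a UCSC cytoBand.txt-layout file into chrom -> [(start, end, band)]."""
    bands: dict[str, list[tuple[int, int, str]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            chrom = normalize_chromosome(fields[0])
            if chrom not in AUTOSOMES:
                continue
            bands.setdefault(chrom, []).append((int(fields[1]), int(fields[2]), fields[3]))
    for lst in bands.values():
        lst.sort()
    return bands


def band_label(
    interval: GenomicInterval, bands: dict[str, list[tuple[int, int, str]]]
) -> str:
    """Display label like ``1p36`` or ``1p36-1p35`` for an interval."""
    chrom_num = interval.chromosome[3:]
    hits = [
        name
        for start, end, name in bands.get(interval.chromosome, [])
        if max(start, interval.start) < min(end, interval.end)
    ]
    if not hits:
        return interval.chromosome
    if len(hits) == 1 or hits[0] == hits[-1]:
        return f"{chrom_num}{hits[0]}"
    return f"{chrom_num}{hits[0]}-{chrom_num}{hits[-1]}"
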