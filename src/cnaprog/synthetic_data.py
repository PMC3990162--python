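"""Synthetic cohort generator with implanted copy-number truth sets.

Builds desk-scale cohorts with the statistical structure the downstream
analysis assumes: progressive patients contribute a graded series of lesions
ending in carcinoma that share a cohort-wide core of progression alterations
and acquire further shared alterations grade by grade; non-progressive and
normal samples carry only germline population CNVs and private alterations.
Probe log2 ratios are the implanted segment means plus iid Gaussian noise.

Implanted intervals are laid out on disjoint genomic "slots" so that events
never collide within or across samples and every event is long enough to be
recoverable by segmentation at the default stringency.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    CNVCatalogEntry,
    Direction,
    GenomicInterval,
    Grade,
    Group,
    ProbeProfile,
    SampleMeta,
    Tobacco,
    read_cnv_catalog,
    read_probe_profile,
    read_sample_sheet,
    write_cnv_catalog,
    write_probe_profile,
    write_sample_sheet,
)

__all__ = [
    "Origin",
    "SimulatedCNA",
    "CohortConfig",
    "Cohort",
    "simulate_patient_series",
    "simulate_cohort",
    "write_fixture",
    "read_fixture",
]

_MIN_GAIN_LOG2 = float(np.log2(1.15))
_MAX_LOSS_LOG2 = float(np.log2(0.85))


class Origin(str, Enum):
    PROGRESSION_CORE = "progression_core"
    GRADE_ACQUIRED = "grade_acquired"
    POPULATION_CNV = "population_cnv"
    PRIVATE = "private"


@dataclass(frozen=True)
class SimulatedCNA:
    """An implanted alteration: where, which way, how strong, and why."""

    interval: GenomicInterval
    direction: Direction
    true_mean_log2: float
    origin: Origin

    def __post_init__(self) -> None:
        if self.direction is Direction.GAIN and self.true_mean_log2 < _MIN_GAIN_LOG2:
            raise ValueError(
                f"gain with true_mean_log2 {self.true_mean_log2} below callable threshold"
            )
        if self.direction is Direction.LOSS and self.true_mean_log2 > _MAX_LOSS_LOG2:
            raise ValueError(
                f"loss with true_mean_log2 {self.true_mean_log2} above callable threshold"
            )


DEFAULT_GRADE_LADDER: tuple[Grade, ...] = (
    Grade.MILD,
    Grade.MODERATE,
    Grade.SEVERE_OR_CIS,
    Grade.CARCINOMA,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-shape and noise parameters; defaults are desk scale.

    ``noise_sd`` defaults to 0.1 on the log2 scale — a modeling choice, not a
    measured value. Effect sizes default to single-copy algebra against a
    diploid baseline: gain log2(3/2) ~= +0.58, loss log2(1/2) = -1.0.
    """

    n_progressive_patients: int = 5
    lesions_per_patient: tuple[Grade, ...] = DEFAULT_GRADE_LADDER
    n_nonprogressive: int = 5
    n_normal: int = 3
    probes_per_chromosome: int = 2000
    probe_spacing: int = 7000
    noise_sd: float = 0.1
    n_core_cnas: int = 4
    n_grade_acquired_per_step: int = 1
    n_private: int = 1
    catalog_size: int = 12
    seed: int = 0
    # layout / effect-size knobs
    n_chromosomes: int = 4
    gain_log2: float = 0.58
    loss_log2: float = -1.0
    gain_fraction: float = 0.75
    n_population_cnv_per_patient: int = 2
    slot_min_probes: int = 36
    slot_max_probes: int = 60
    gap_min_probes: int = 12
    gap_max_probes: int = 24
    edge_margin_probes: int = 20

    def __post_init__(self) -> None:
        counts = (
            self.n_progressive_patients, self.n_nonprogressive, self.n_normal,
            self.probes_per_chromosome, self.n_core_cnas,
            self.n_grade_acquired_per_step, self.n_private, self.catalog_size,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.n_chromosomes <= 22:
            raise ValueError("n_chromosomes must be in 1..22")
        if self.lesions_per_patient and self.lesions_per_patient[-1] is not Grade.CARCINOMA:
            raise ValueError("the grade ladder must end in carcinoma")
        if self.gain_log2 < _MIN_GAIN_LOG2 or self.loss_log2 > _MAX_LOSS_LOG2:
            raise ValueError("implanted effect sizes must be callable in expectation")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i}" for i in range(1, self.n_chromosomes + 1))


@dataclass
class Cohort:
    profiles: list[ProbeProfile]
    metas: list[SampleMeta]
    truth: dict[str, list[SimulatedCNA]]
    catalog: list[CNVCatalogEntry]


# ---------------------------------------------------------------------------
# Slot layout
# ---------------------------------------------------------------------------

class _SlotAllocator:
    """Hands out disjoint probe-index ranges so implants never collide."""

    def __init__(self, config: CohortConfig, rng: np.random.Generator) -> None:
        slots: list[tuple[str, int, int]] = []
        for chrom in config.chromosomes:
            i = config.edge_margin_probes
            limit = config.probes_per_chromosome - config.edge_margin_probes
            while True:
                length = int(rng.integers(config.slot_min_probes, config.slot_max_probes + 1))
                if i + length > limit:
                    break
                slots.append((chrom, i, i + length))
                i += length + int(rng.integers(config.gap_min_probes, config.gap_max_probes + 1))
        rng.shuffle(slots)
        self._slots = slots
        self._spacing = config.probe_spacing

    def take(self) -> GenomicInterval:
        if not self._slots:
            raise RuntimeError(
                "ran out of genomic slots; increase probes_per_chromosome or "
                "n_chromosomes, or reduce event counts"
            )
        chrom, i0, i1 = self._slots.pop()
        # probes are points at i*spacing; the interval covers first..last probe
        return GenomicInterval(chrom, i0 * self._spacing, (i1 - 1) * self._spacing + 1)

    def remaining(self) -> int:
        return len(self._slots)


def _draw_cna(
    config: CohortConfig, allocator: _SlotAllocator, rng: np.random.Generator, origin: Origin
) -> SimulatedCNA:
    interval = allocator.take()
    if rng.random() < config.gain_fraction:
        return SimulatedCNA(interval, Direction.GAIN, config.gain_log2, origin)
    return SimulatedCNA(interval, Direction.LOSS, config.loss_log2, origin)


# ---------------------------------------------------------------------------
# Pools shared across the cohort
# ---------------------------------------------------------------------------

@dataclass
class _SharedPools:
    core: list[SimulatedCNA]
    acquired_per_step: list[list[SimulatedCNA]]  # index: grade step >= 1
    catalog: list[CNVCatalogEntry]
    common_catalog: list[CNVCatalogEntry]


def _build_pools(
    config: CohortConfig, allocator: _SlotAllocator, rng: np.random.Generator
) -> _SharedPools:
    catalog: list[CNVCatalogEntry] = []
    for j in range(config.catalog_size):
        interval = allocator.take()
        direction = Direction.GAIN if rng.random() < config.gain_fraction else Direction.LOSS
        # alternate common and rare entries so the population filter sees both
        freq = float(rng.uniform(0.05, 0.5)) if j % 2 == 0 else float(rng.uniform(0.0, 0.005))
        catalog.append(CNVCatalogEntry(interval, direction, freq))
    core = [
        _draw_cna(config, allocator, rng, Origin.PROGRESSION_CORE)
        for _ in range(config.n_core_cnas)
    ]
    acquired = [
        [
            _draw_cna(config, allocator, rng, Origin.GRADE_ACQUIRED)
            for _ in range(config.n_grade_acquired_per_step)
        ]
        for _ in range(max(len(config.lesions_per_patient) - 1, 0))
    ]
    common = [e for e in catalog if e.population_frequency > 0.01]
    return _SharedPools(core=core, acquired_per_step=acquired, catalog=catalog, common_catalog=common)


def _patient_germline(
    pools: _SharedPools, config: CohortConfig, rng: np.random.Generator
) -> list[SimulatedCNA]:
    """Per-patient germline CNVs, drawn from the common catalog entries."""
    n = min(config.n_population_cnv_per_patient, len(pools.common_catalog))
    if n == 0:
        return []
    picks = rng.choice(len(pools.common_catalog), size=n, replace=False)
    out = []
    for j in sorted(int(k) for k in picks):
        entry = pools.common_catalog[j]
        mean = config.gain_log2 if entry.direction is Direction.GAIN else config.loss_log2
        out.append(SimulatedCNA(entry.interval, entry.direction, mean, Origin.POPULATION_CNV))
    return out


# ---------------------------------------------------------------------------
# Profile synthesis
# ---------------------------------------------------------------------------

def _synthesize_profile(
    sample_id: str,
    cnas: Sequence[SimulatedCNA],
    config: CohortConfig,
    rng: np.random.Generator,
) -> ProbeProfile:
    spacing = config.probe_spacing
    n = config.probes_per_chromosome
    chroms: list[str] = []
    positions: list[int] = []
    values: list[np.ndarray] = []
    by_chrom: dict[str, list[SimulatedCNA]] = {}
    for cna in cnas:
        by_chrom.setdefault(cna.interval.chromosome, []).append(cna)
    for chrom in config.chromosomes:
        vals = config.noise_sd * rng.standard_normal(n)
        for cna in by_chrom.get(chrom, []):
            i0 = cna.interval.start // spacing
            i1 = (cna.interval.end - 1) // spacing + 1
            vals[i0:i1] += cna.true_mean_log2
        chroms.extend([chrom] * n)
        positions.extend(range(0, n * spacing, spacing))
        values.append(vals)
    return ProbeProfile(sample_id, chroms, positions, np.concatenate(values))


def _simulate_patient(
    config: CohortConfig,
    patient_id: str,
    rng: np.random.Generator,
    pools: _SharedPools,
    allocator: _SlotAllocator,
    tobacco: Tobacco,
) -> tuple[list[ProbeProfile], list[SampleMeta], dict[str, list[SimulatedCNA]]]:
    ladder = config.lesions_per_patient
    germline = _patient_germline(pools, config, rng)
    profiles: list[ProbeProfile] = []
    metas: list[SampleMeta] = []
    truth: dict[str, list[SimulatedCNA]] = {}
    acquired_so_far: list[SimulatedCNA] = []
    for step, grade in enumerate(ladder):
        if step >= 1 and step - 1 < len(pools.acquired_per_step):
            acquired_so_far = acquired_so_far + pools.acquired_per_step[step - 1]
        private = [
            _draw_cna(config, allocator, rng, Origin.PRIVATE)
            for _ in range(config.n_private)
        ]
        sample_id = f"{patient_id}L{step + 1}"
        cnas = list(pools.core) + list(acquired_so_far) + private + germline
        group = Group.OSCC if grade is Grade.CARCINOMA else Group.PL
        metas.append(
            SampleMeta(
                sample_id=sample_id,
                patient_id=patient_id,
                group=group,
                grade=grade,
                lesion_order=step + 1,
                tobacco=tobacco,
            )
        )
        profiles.append(_synthesize_profile(sample_id, cnas, config, rng))
        truth[sample_id] = cnas
    return profiles, metas, truth


def simulate_patient_series(
    config: CohortConfig, patient_id: str, rng: np.random.Generator
) -> tuple[list[ProbeProfile], list[SampleMeta], dict[str, list[SimulatedCNA]]]:
    """Simulate one progressive patient's graded lesion series.

    Core alterations are present in every lesion; grade-acquired alterations
    are present from their grade of origin onward (monotone presence). Probe
    log2 values are the implanted mean plus iid Gaussian(0, noise_sd).
    """
    allocator = _SlotAllocator(config, rng)
    pools = _build_pools(replace(config, catalog_size=0), allocator, rng)
    return _simulate_patient(config, patient_id, rng, pools, allocator, Tobacco.YES)


_NPL_GRADES = (Grade.MILD, Grade.MODERATE, Grade.SEVERE_OR_CIS)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate the full cohort: progressive series, non-progressive and
    normal controls, and the population CNV catalog. Deterministic under a
    fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    allocator = _SlotAllocator(config, rng)
    pools = _build_pools(config, allocator, rng)

    profiles: list[ProbeProfile] = []
    metas: list[SampleMeta] = []
    truth: dict[str, list[SimulatedCNA]] = {}

    for k in range(config.n_progressive_patients):
        tobacco = Tobacco.YES if rng.random() < 0.85 else Tobacco.NO
        p_profiles, p_metas, p_truth = _simulate_patient(
            config, f"P{k + 1}", rng, pools, allocator, tobacco
        )
        profiles.extend(p_profiles)
        metas.extend(p_metas)
        truth.update(p_truth)

    for k in range(config.n_nonprogressive):
        patient_id = f"N{k + 1}"
        sample_id = f"{patient_id}S1"
        germline = _patient_germline(pools, config, rng)
        private = [
            _draw_cna(config, allocator, rng, Origin.PRIVATE)
            for _ in range(config.n_private)
        ]
        tobacco = Tobacco.YES if rng.random() < 0.3 else Tobacco.NO
        metas.append(
            SampleMeta(
                sample_id=sample_id,
                patient_id=patient_id,
                group=Group.NPL,
                grade=_NPL_GRADES[k % len(_NPL_GRADES)],
                lesion_order=1,
                tobacco=tobacco,
            )
        )
        cnas = germline + private
        profiles.append(_synthesize_profile(sample_id, cnas, config, rng))
        truth[sample_id] = cnas

    for k in range(config.n_normal):
        patient_id = f"C{k + 1}"
        sample_id = f"{patient_id}S1"
        germline = _patient_germline(pools, config, rng)
        metas.append(
            SampleMeta(
                sample_id=sample_id,
                patient_id=patient_id,
                group=Group.NORMAL,
                grade=Grade.NON_DYSPLASTIC,
                lesion_order=1,
                tobacco=Tobacco.UNKNOWN,
            )
        )
        profiles.append(_synthesize_profile(sample_id, germline, config, rng))
        truth[sample_id] = list(germline)

    return Cohort(profiles=profiles, metas=metas, truth=truth, catalog=pools.catalog)


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------

def write_fixture(cohort: Cohort, directory: str | Path) -> None:
    """Write the cohort as plain-text files: one probe TSV per sample, a
    sample sheet CSV, the catalog BED, and a truth BED."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for profile in cohort.profiles:
        write_probe_profile(profile, directory / f"{profile.sample_id}.probes.tsv")
    write_sample_sheet(cohort.metas, directory / "samples.csv")
    write_cnv_catalog(cohort.catalog, directory / "catalog.bed")
    with (directory / "truth.bed").open("w") as fh:
        for meta in cohort.metas:
            for cna in cohort.truth[meta.sample_id]:
                iv = cna.interval
                fh.write(
                    f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{meta.sample_id}\t"
                    f"{cna.true_mean_log2!r}\t{cna.direction.value}\t{cna.origin.value}\n"
                )


def read_fixture(directory: str | Path) -> Cohort:
    """Read a fixture written by :func:`write_fixture` back into memory."""
    directory = Path(directory)
    metas = read_sample_sheet(directory / "samples.csv")
    profiles = [
        read_probe_profile(directory / f"{m.sample_id}.probes.tsv", m.sample_id)
        for m in metas
    ]
    catalog = read_cnv_catalog(directory / "catalog.bed")
    truth: dict[str, list[SimulatedCNA]] = {m.sample_id: [] for m in metas}
    with (directory / "truth.bed").open() as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            truth[fields[3]].append(
                SimulatedCNA(
                    interval=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    direction=Direction(fields[5]),
                    true_mean_log2=float(fields[4]),
                    origin=Origin(fields[6]),
                )
            )
    return Cohort(profiles=profiles, metas=metas, truth=truth, catalog=catalog)


def fixture_digest(directory: str | Path) -> str:
    """SHA-256 over every fixture file (sorted by name); determinism check."""
    h = hashlib.sha256()
    for path in sorted(Path(directory).iterdir()):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
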