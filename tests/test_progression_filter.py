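import numpy as np
import pytest

from cnaprog.core_io import (
    CNACall,
    CNVCatalogEntry,
    Direction,
    GenomicInterval,
    Grade,
    Group,
    SampleMeta,
    Segment,
    Tobacco,
    reciprocal_overlap,
)
from cnaprog.progression_filter import (
    FilterReport,
    RecurrentRegion,
    SequentialClass,
    build_recurrent_regions,
    cluster_calls,
    filter_population_cnvs,
    frequency_table,
    locus_in_regions,
    run_filter_cascade,
    sequential_recurrence,
    subtract_group_cnas,
)
from cnaprog.synthetic_data import Origin

from oracles import brute_force_overlap_clusters


def call(chrom, start, end, direction=Direction.GAIN, mean=0.5):
    if direction is Direction.LOSS:
        mean = -abs(mean)
    seg = Segment(GenomicInterval(chrom, start, end), mean, 10, 0.05)
    return CNACall(segment=seg, direction=direction)


def entry(chrom, start, end, direction=Direction.GAIN, freq=0.2):
    return CNVCatalogEntry(GenomicInterval(chrom, start, end), direction, freq)


def meta(sid, pid, group, grade, order, tobacco=Tobacco.UNKNOWN):
    return SampleMeta(sid, pid, group, grade, order, tobacco)


def random_calls(rng, n, chroms=("chr1", "chr2"), direction_mix=True):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, 2_000_000))
        length = int(rng.integers(5_000, 120_000))
        direction = (
            Direction.GAIN if not direction_mix or rng.random() < 0.6 else Direction.LOSS
        )
        out.append(call(chrom, start, start + length, direction))
    return out


class TestPopulationCnvFilter:
    def test_exact_match_above_cap_removed(self):
        c = call("chr1", 0, 1000)
        kept, removed = filter_population_cnvs([c], [entry("chr1", 0, 1000, freq=0.2)],
                                               max_population_frequency=0.01)
        assert kept == [] and removed == [c]

    def test_direction_mismatch_kept(self):
        c = call("chr1", 0, 1000, Direction.GAIN)
        kept, removed = filter_population_cnvs(
            [c], [entry("chr1", 0, 1000, Direction.LOSS, freq=0.2)]
        )
        assert kept == [c] and removed == []

    def test_rare_variant_kept(self):
        c = call("chr1", 0, 1000)
        kept, removed = filter_population_cnvs(
            [c], [entry("chr1", 0, 1000, freq=0.005)], max_population_frequency=0.01
        )
        assert kept == [c] and removed == []

    def test_below_overlap_threshold_kept(self):
        c = call("chr1", 0, 1000)
        kept, _ = filter_population_cnvs(
            [c], [entry("chr1", 700, 1700, freq=0.2)], min_reciprocal_overlap=0.5
        )
        assert kept == [c]

    def test_neutral_call_rejected(self):
        seg = Segment(GenomicInterval("chr1", 0, 1000), 0.0, 10, 0.05)
        with pytest.raises(ValueError):
            filter_population_cnvs([CNACall(seg, Direction.NEUTRAL)], [])

    def test_conservation(self, rng):
        calls = random_calls(rng, 100)
        catalog = [
            entry("chr1", int(s), int(s) + 50_000, freq=float(f))
            for s, f in zip(rng.integers(0, 2_000_000, 30), rng.uniform(0, 0.3, 30))
        ]
        kept, removed = filter_population_cnvs(calls, catalog)
        assert len(kept) + len(removed) == len(calls)
        assert {id(c) for c in kept} | {id(c) for c in removed} == {id(c) for c in calls}


class TestSubtraction:
    def test_coinciding_call_removed(self):
        prog = [call("chr1", 0, 1000), call("chr1", 5000, 9000), call("chr2", 0, 1000)]
        nonprog = [call("chr1", 0, 1000)]
        kept, removed = subtract_group_cnas(prog, nonprog)
        assert len(kept) == 2 and removed == [prog[0]]

    def test_empty_nonprogressive_is_identity(self, rng):
        prog = random_calls(rng, 20)
        kept, removed = subtract_group_cnas(prog, [])
        assert kept == prog and removed == []

    def test_quadratic_oracle(self, rng):
        prog = random_calls(rng, 200)
        nonprog = random_calls(rng, 60)
        kept, removed = subtract_group_cnas(prog, nonprog, 0.5)
        expected_removed = set()
        for i, p in enumerate(prog):
            for q in nonprog:
                if (
                    p.direction is q.direction
                    and reciprocal_overlap(p.interval, q.interval) >= 0.5
                ):
                    expected_removed.add(i)
        assert {prog.index(c) for c in removed} == expected_removed
        assert len(kept) + len(removed) == len(prog)

    def test_order_invariance(self, rng):
        prog = random_calls(rng, 50)
        nonprog = random_calls(rng, 20)
        kept1, _ = subtract_group_cnas(prog, nonprog)
        perm = list(rng.permutation(len(prog)))
        kept2, _ = subtract_group_cnas([prog[i] for i in perm], nonprog[::-1])
        assert {id(c) for c in kept1} == {id(c) for c in kept2}


class TestFilterCascade:
    def test_counts_monotone_and_conserved(self, rng):
        prog = random_calls(rng, 150)
        nonprog = random_calls(rng, 50)
        catalog = [
            entry("chr1", int(s), int(s) + 60_000, freq=float(f))
            for s, f in zip(rng.integers(0, 2_000_000, 25), rng.uniform(0, 0.3, 25))
        ]
        kept, report = run_filter_cascade(prog, nonprog, catalog)
        assert report.n_input >= report.n_after_cnv_filter >= report.n_after_subtraction
        assert report.n_after_subtraction == len(kept)
        assert len(kept) + len(report.removed) == len(prog)

    def test_report_validation(self):
        report = FilterReport(n_input=5, n_after_cnv_filter=7, n_after_subtraction=2)
        with pytest.raises(ValueError):
            report.validate()


def two_group_metas():
    return [
        meta(f"s{i}", f"p{i}", Group.PL, Grade.MILD, 1) for i in range(1, 26)
    ]


class TestRecurrentRegions:
    def test_frequency_20_of_25(self):
        metas = two_group_metas()
        calls = {
            f"s{i}": [call("chr1", 1_000_000, 1_100_000)] for i in range(1, 21)
        }
        calls["s21"] = [call("chr2", 0, 50_000)]
        regions = build_recurrent_regions(calls, metas)
        chr1 = [r for r in regions if r.interval.chromosome == "chr1"]
        assert len(chr1) == 1
        assert chr1[0].frequency == pytest.approx(0.80)
        assert len(chr1[0].samples_present) == 20

    def test_different_chromosomes_two_regions(self):
        metas = two_group_metas()
        calls = {"s1": [call("chr1", 0, 1000)], "s2": [call("chr2", 0, 1000)]}
        regions = build_recurrent_regions(calls, metas)
        assert len(regions) == 2

    def test_identical_intervals_minimal_equals_interval(self):
        metas = two_group_metas()
        calls = {f"s{i}": [call("chr1", 500, 1500)] for i in (1, 2, 3)}
        [region] = build_recurrent_regions(calls, metas)
        assert region.minimal_region == region.interval == GenomicInterval("chr1", 500, 1500)

    def test_minimal_region_is_intersection(self):
        metas = two_group_metas()
        calls = {
            "s1": [call("chr1", 0, 10_000)],
            "s2": [call("chr1", 2_000, 12_000)],
        }
        [region] = build_recurrent_regions(calls, metas)
        assert region.interval == GenomicInterval("chr1", 0, 12_000)
        assert region.minimal_region == GenomicInterval("chr1", 2_000, 10_000)

    def test_chain_with_empty_intersection_uses_depth_core(self):
        # a-b and b-c overlap at >=50% but a-c are disjoint: single-linkage
        # chains them; the minimal region falls back to the deepest core
        metas = two_group_metas()
        calls = {
            "s1": [call("chr1", 0, 1000)],
            "s2": [call("chr1", 500, 1500)],
            "s3": [call("chr1", 1000, 2000)],
        }
        [region] = build_recurrent_regions(calls, metas)
        assert region.interval == GenomicInterval("chr1", 0, 2000)
        # depth 2 holds contiguously on [500,1500): the maximal run at max depth
        assert region.minimal_region == GenomicInterval("chr1", 500, 1500)

    def test_direction_never_mixes(self):
        metas = two_group_metas()
        calls = {
            "s1": [call("chr1", 0, 1000, Direction.GAIN)],
            "s2": [call("chr1", 0, 1000, Direction.LOSS)],
        }
        regions = build_recurrent_regions(calls, metas)
        assert len(regions) == 2
        assert {r.direction for r in regions} == {Direction.GAIN, Direction.LOSS}

    def test_order_invariance(self, rng):
        metas = two_group_metas()
        base = {f"s{i}": random_calls(rng, 6) for i in range(1, 9)}
        regions1 = build_recurrent_regions(base, metas)
        shuffled = {k: list(reversed(v)) for k, v in reversed(list(base.items()))}
        regions2 = build_recurrent_regions(shuffled, metas)
        key = lambda r: (r.interval, r.direction.value, tuple(sorted(r.samples_present)))
        assert sorted(map(key, regions1)) == sorted(map(key, regions2))

    def test_union_find_oracle(self, rng):
        flat = [(f"s{i % 12}", c) for i, c in enumerate(random_calls(rng, 500))]
        clusters = cluster_calls(flat, 0.5)
        items = [
            (c.interval.chromosome, c.interval.start, c.interval.end, c.direction.value)
            for _, c in flat
        ]
        expected = {frozenset(g) for g in brute_force_overlap_clusters(items, 0.5)}
        assert {frozenset(c) for c in clusters} == expected


def series_metas():
    return [
        meta("L1", "p1", Group.PL, Grade.MILD, 1),
        meta("L2", "p1", Group.PL, Grade.SEVERE_OR_CIS, 2),
        meta("T", "p1", Group.OSCC, Grade.CARCINOMA, 3),
        meta("N1", "n1", Group.NPL, Grade.MILD, 1),
    ]


def region_with(samples, chrom="chr1", start=0, end=1000):
    return RecurrentRegion(
        interval=GenomicInterval(chrom, start, end),
        direction=Direction.GAIN,
        samples_present=frozenset(samples),
        frequency=len(samples) / 3,
        minimal_region=GenomicInterval(chrom, start, end),
    )


class TestSequentialRecurrence:
    def test_oscc_and_preceding_not_all(self):
        [rc] = sequential_recurrence([region_with({"L2", "T"})], series_metas())
        assert rc.overall is SequentialClass.IN_OSCC_AND_PRECEDING_OPML
        assert rc.per_patient["p1"] is SequentialClass.IN_OSCC_AND_PRECEDING_OPML

    def test_only_in_oscc_is_other(self):
        [rc] = sequential_recurrence([region_with({"T"})], series_metas())
        assert rc.overall is SequentialClass.OTHER

    def test_all_sequential(self):
        [rc] = sequential_recurrence([region_with({"L1", "L2", "T"})], series_metas())
        assert rc.overall is SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES
        assert rc.n_patients_in_all == 1

    def test_patient_without_oscc_skipped(self, caplog):
        metas = [
            meta("L1", "p1", Group.PL, Grade.MILD, 1),
            meta("L2", "p2", Group.PL, Grade.MILD, 1),
            meta("T2", "p2", Group.OSCC, Grade.CARCINOMA, 2),
        ]
        [rc] = sequential_recurrence([region_with({"L1", "L2", "T2"})], metas)
        assert "p1" not in rc.per_patient
        assert rc.per_patient["p2"] is SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES

    def test_core_truth_classified_in_all(self, default_cohort, cohort_calls, progressive_sample_ids):
        """Every implanted progression-core alteration is in_all for its patient."""
        metas = default_cohort.metas
        per_sample = {s: cohort_calls[s] for s in progressive_sample_ids}
        regions = build_recurrent_regions(per_sample, metas)
        classes = sequential_recurrence(regions, metas)
        cores = {
            (c.interval, c.direction)
            for s in progressive_sample_ids
            for c in default_cohort.truth[s]
            if c.origin is Origin.PROGRESSION_CORE
        }
        for iv, d in cores:
            matching = [
                rc for rc in classes
                if rc.region.direction is d
                and reciprocal_overlap(rc.region.interval, iv) >= 0.5
            ]
            assert matching, f"no region recovered for core truth {iv}"
            assert any(
                rc.overall is SequentialClass.IN_ALL_SEQUENTIAL_SAMPLES for rc in matching
            )


class TestFrequencyTable:
    def test_17_of_25_is_68_percent(self):
        metas = two_group_metas()
        region = RecurrentRegion(
            interval=GenomicInterval("chr1", 0, 1000),
            direction=Direction.GAIN,
            samples_present=frozenset(f"s{i}" for i in range(1, 18)),
            frequency=17 / 25,
            minimal_region=GenomicInterval("chr1", 0, 1000),
        )
        table = frequency_table([region], metas)
        assert table.loc[0, "n_present"] == 17
        assert table.loc[0, "n_group"] == 25
        assert table.loc[0, "percent"] == pytest.approx(68.0)

    def test_absent_region_omitted(self):
        metas = two_group_metas()
        region = region_with({"zz"})
        assert len(frequency_table([region], metas)) == 0

    def test_percent_self_consistent_and_sorted(self, rng):
        metas = two_group_metas()
        regions = []
        for k, n in enumerate((5, 20, 12)):
            regions.append(
                RecurrentRegion(
                    interval=GenomicInterval("chr1", k * 10_000, k * 10_000 + 1000),
                    direction=Direction.GAIN,
                    samples_present=frozenset(f"s{i}" for i in range(1, n + 1)),
                    frequency=n / 25,
                    minimal_region=GenomicInterval("chr1", k * 10_000, k * 10_000 + 1000),
                )
            )
        table = frequency_table(regions, metas)
        recomputed = 100.0 * table["n_present"] / table["n_group"]
        assert np.allclose(table["percent"], recomputed)
        assert list(table["percent"]) == sorted(table["percent"], reverse=True)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            frequency_table([], [meta("n", "n", Group.NPL, Grade.MILD, 1)],
                            groups=(Group.PL, Group.OSCC))


class TestLocusInRegions:
    def setup_method(self):
        self.regions = [region_with({"s1", "s2"}, start=1000, end=2000)]

    def test_point_inside(self):
        hits = locus_in_regions(GenomicInterval("chr1", 1500, 1501), self.regions)
        assert hits == self.regions

    def test_boundary_end_excluded(self):
        assert locus_in_regions(GenomicInterval("chr1", 2000, 2001), self.regions) == []

    def test_no_match(self):
        assert locus_in_regions(GenomicInterval("chr2", 1500, 1501), self.regions) == []
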