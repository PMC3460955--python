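"""Cross-sample recurrence: frequencies, minimal common regions, annotation."""

import numpy as np
import pytest

from gbmcna import (
    AMPLIFICATION,
    HOMOZYGOUS_DELETION,
    CnaEvent,
    GeneModel,
    GenomicInterval,
    annotate_genes,
    cooccurrence_matrix,
    minimal_common_region,
    recurrence_frequency,
)
from gbmcna.recurrence import coverage_segments


def ev(sample, chrom, start, end, kind=HOMOZYGOUS_DELETION):
    return CnaEvent(sample, chrom, start, end, kind, n_probes=5, mean_cn=(
        0.2 if kind == HOMOZYGOUS_DELETION else 7.0))


CDKN2A = GenomicInterval("chr9", 21_978_443, 22_119_128)


class TestRecurrenceFrequency:
    @pytest.mark.parametrize(
        "n_cases,expected_pct",
        [(24, 52), (12, 26), (4, 9), (3, 7), (21, 46)],
    )
    def test_printed_count_percent_pairs(self, n_cases, expected_pct):
        """The integer rounding reproduces every printed n/46 -> % pair."""
        events = [
            ev(f"G{i}", "chr9", 21_900_000, 22_200_000) for i in range(n_cases)
        ]
        assert recurrence_frequency(events, CDKN2A, HOMOZYGOUS_DELETION, 46) == (
            n_cases,
            expected_pct,
        )

    def test_no_events(self):
        assert recurrence_frequency([], CDKN2A, HOMOZYGOUS_DELETION, 46) == (0, 0)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            recurrence_frequency([], CDKN2A, HOMOZYGOUS_DELETION, 0)

    def test_case_counted_once_despite_multiple_events(self):
        events = [
            ev("G1", "chr9", 21_900_000, 22_000_000),
            ev("G1", "chr9", 22_050_000, 22_200_000),
        ]
        assert recurrence_frequency(events, CDKN2A, HOMOZYGOUS_DELETION, 46)[0] == 1

    def test_kind_and_overlap_filtering(self):
        events = [
            ev("G1", "chr9", 21_900_000, 22_200_000, kind=AMPLIFICATION),
            ev("G2", "chr9", 1_000, 2_000),  # no overlap
            ev("G3", "chr10", 21_978_443, 22_119_128),  # wrong chromosome
        ]
        assert recurrence_frequency(events, CDKN2A, HOMOZYGOUS_DELETION, 46) == (0, 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_frequency_monotone_in_region_size(self, seed):
        rng = np.random.default_rng(seed)
        events = [
            ev(f"G{i}", "chr9", s := int(rng.integers(1, 5000)), s + int(rng.integers(1, 500)))
            for i in range(15)
        ]
        small = GenomicInterval("chr9", 2000, 2500)
        large = GenomicInterval("chr9", 1500, 3500)
        n_small, _ = recurrence_frequency(events, small, HOMOZYGOUS_DELETION, 46)
        n_large, _ = recurrence_frequency(events, large, HOMOZYGOUS_DELETION, 46)
        assert n_large >= n_small


def brute_force_mcr(events, kind, min_cases, max_coord=5000):
    """Per-base coverage scan: independent oracle on small coordinates."""
    events = [e for e in events if e.kind == kind]
    by_chrom = sorted({e.chrom for e in events})
    out = []
    for chrom in by_chrom:
        cases = sorted({e.sample_id for e in events if e.chrom == chrom})
        cov = np.zeros(max_coord + 2, dtype=int)
        per_case = {}
        for case in cases:
            mask = np.zeros(max_coord + 2, dtype=bool)
            for e in events:
                if e.chrom == chrom and e.sample_id == case:
                    mask[e.start : e.end + 1] = True
            per_case[case] = mask
            cov += mask
        # maximal runs with coverage >= min_cases
        above = cov >= min_cases
        pos = 1
        while pos <= max_coord:
            if not above[pos]:
                pos += 1
                continue
            comp_start = pos
            while pos <= max_coord and above[pos]:
                pos += 1
            comp_end = pos - 1
            peak = cov[comp_start : comp_end + 1].max()
            # maximal plateaus at the peak
            q = comp_start
            while q <= comp_end:
                if cov[q] != peak:
                    q += 1
                    continue
                p_start = q
                while q <= comp_end and cov[q] == peak:
                    q += 1
                p_end = q - 1
                carriers = tuple(
                    c for c in cases if per_case[c][p_start : p_end + 1].all()
                )
                out.append((chrom, p_start, p_end, carriers))
    return out


class TestMinimalCommonRegion:
    def test_pairwise_intersection(self):
        events = [ev("A", "chr1", 100, 500), ev("B", "chr1", 300, 900)]
        regions = minimal_common_region(events, HOMOZYGOUS_DELETION, 2)
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end) == (300, 500)
        assert r.case_ids == ("A", "B")
        assert r.n_cases == 2
        assert r.length_bp == 200

    def test_single_sample_below_min_cases(self):
        assert minimal_common_region([ev("A", "chr1", 100, 500)], HOMOZYGOUS_DELETION, 2) == []

    def test_frequency_pct_uses_cohort_size(self):
        events = [ev(s, "chr9", 100, 500) for s in ("A", "B", "C")]
        (r,) = minimal_common_region(events, HOMOZYGOUS_DELETION, 2, cohort_size=46)
        assert r.frequency_pct == 7  # 3/46

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        events = []
        for i in range(int(rng.integers(2, 20))):
            s = int(rng.integers(1, 4500))
            events.append(
                ev(f"S{rng.integers(0, 8)}", "chr1", s, s + int(rng.integers(1, 400)))
            )
        min_cases = int(rng.integers(2, 4))
        got = [
            (r.interval.chrom, r.interval.start, r.interval.end, r.case_ids)
            for r in minimal_common_region(events, HOMOZYGOUS_DELETION, min_cases)
        ]
        assert got == brute_force_mcr(events, HOMOZYGOUS_DELETION, min_cases)

    @pytest.mark.parametrize("seed", range(4))
    def test_mcr_contained_in_every_contributor(self, seed):
        rng = np.random.default_rng(100 + seed)
        events = []
        for i in range(12):
            s = int(rng.integers(1, 4000))
            events.append(ev(f"S{i % 5}", "chr1", s, s + int(rng.integers(50, 800))))
        for r in minimal_common_region(events, HOMOZYGOUS_DELETION, 2):
            for case in r.case_ids:
                covered = any(
                    e.start <= r.interval.start and r.interval.end <= e.end
                    for e in events
                    if e.sample_id == case
                ) or _merged_covers(events, case, r.interval)
                assert covered

    def test_pileup_conserves_total_event_length(self):
        rng = np.random.default_rng(11)
        events = []
        for i in range(10):
            s = int(rng.integers(1, 3000))
            events.append(ev(f"S{i % 4}", "chr1", s, s + int(rng.integers(10, 500))))
        segs = coverage_segments(events)
        pileup_mass = sum((b - a) * c for a, b, c in segs)
        # merged per-case lengths (bp counts, end-inclusive)
        total = 0
        for case in {e.sample_id for e in events}:
            mask = np.zeros(5000, dtype=bool)
            for e in events:
                if e.sample_id == case:
                    mask[e.start : e.end + 1] = True
            total += int(mask.sum())
        assert pileup_mass == total


def _merged_covers(events, case, interval):
    lo = min(e.start for e in events if e.sample_id == case)
    hi = max(e.end for e in events if e.sample_id == case)
    mask = np.zeros(hi + 2, dtype=bool)
    for e in events:
        if e.sample_id == case:
            mask[e.start : e.end + 1] = True
    return mask[interval.start : interval.end + 1].all()


GENES_9P21 = [
    GeneModel("MTAP", "chr9", 21_800_001, 21_900_000),
    GeneModel("CDKN2A", "chr9", 21_978_443, 22_119_128),
    GeneModel("CDKN2B", "chr9", 22_190_001, 22_290_000),
]


class TestGeneAnnotation:
    def test_region_between_genes_annotates_nothing(self):
        region = GenomicInterval("chr9", 21_950_000, 21_970_000)
        assert annotate_genes(region, GENES_9P21) == []

    def test_fully_spanned_gene_included(self):
        region = GenomicInterval("chr9", 21_700_000, 21_950_000)
        assert annotate_genes(region, GENES_9P21) == ["MTAP"]

    def test_mcr_covering_cdkn2a_and_cdkn2b(self):
        region = GenomicInterval("chr9", 21_978_443, 22_200_000)
        assert annotate_genes(region, GENES_9P21) == ["CDKN2A", "CDKN2B"]


class TestCooccurrence:
    REGIONS = {
        "chr4_amp": (GenomicInterval("chr4", 54_000_001, 56_000_000), AMPLIFICATION),
        "chr7_amp": (GenomicInterval("chr7", 54_500_001, 56_000_000), AMPLIFICATION),
        "chr12_amp": (GenomicInterval("chr12", 56_000_001, 58_000_000), AMPLIFICATION),
    }

    def test_no_events_all_zero(self):
        table = cooccurrence_matrix([], self.REGIONS, case_ids=["G1", "G2"])
        assert (table.to_numpy() == 0).all()

    def test_triple_amplicon_case(self):
        """A case with amplicons on chromosomes 4, 7 and 12 has three 1s."""
        events = [
            ev("G82", "chr4", 54_500_001, 55_000_000, kind=AMPLIFICATION),
            ev("G82", "chr7", 55_000_001, 55_500_000, kind=AMPLIFICATION),
            ev("G82", "chr12", 56_500_001, 57_000_000, kind=AMPLIFICATION),
            ev("G88", "chr4", 54_500_001, 55_000_000, kind=AMPLIFICATION),
            ev("G88", "chr12", 56_500_001, 57_000_000, kind=AMPLIFICATION),
        ]
        table = cooccurrence_matrix(events, self.REGIONS)
        assert table.loc["G82"].sum() == 3
        assert table.loc["G88"].sum() == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_row_sums_match_recount(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr4", "chr7", "chr12"]
        events = []
        for i in range(20):
            c = chroms[int(rng.integers(0, 3))]
            s = int(rng.integers(54_000_001, 57_000_000))
            events.append(ev(f"G{rng.integers(0, 6)}", c, s, s + 200_000, kind=AMPLIFICATION))
        table = cooccurrence_matrix(events, self.REGIONS)
        for case in table.index:
            expected = sum(
                any(
                    e.sample_id == case and e.kind == kind and e.interval.overlaps(iv)
                    for e in events
                )
                for iv, kind in self.REGIONS.values()
            )
            assert table.loc[case].sum() == expected
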