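"""Signature statistics against quadratic brute-force pair enumeration, the
empirical null, and the planted-structure response."""

import numpy as np
import pytest

from mobilome_trap.core_io import AlignmentRecord, GenomicInterval
from mobilome_trap.signatures import (
    filter_pirna_alignments,
    length_distribution,
    phasing_zscore,
    pingpong_zscore,
    stranded_coverage,
)
from mobilome_trap.synthetic import simulate_small_rna_library

from conftest import make_record, random_records


# ---------------------------------------------------------------------------
# Brute-force oracles: enumerate every placement pair.
# ---------------------------------------------------------------------------

def brute_pingpong_counts(records):
    counts = np.zeros(20)
    plus = [r for r in records if r.interval.strand == "+"]
    minus = [r for r in records if r.interval.strand == "-"]
    for p in plus:
        for m in minus:
            if p.interval.chrom != m.interval.chrom:
                continue
            overlap = m.five_prime - p.five_prime + 1
            if 1 <= overlap <= 20:
                counts[overlap - 1] += 1
    return counts


def brute_phasing_counts(records):
    counts = np.zeros(20)
    for up in records:
        for down in records:
            if up is down:
                continue
            if up.interval.strand != down.interval.strand:
                continue
            if up.interval.chrom != down.interval.chrom:
                continue
            if up.interval.strand == "+":
                d = down.interval.start - up.interval.end + 1
            else:
                d = up.interval.start - down.interval.end + 1
            if 0 <= d <= 19:
                counts[d] += 1
    return counts


def brute_coverage(records, region):
    sense = np.zeros(len(region))
    anti = np.zeros(len(region))
    for r in records:
        for pos in range(r.interval.start, r.interval.end):
            if r.interval.chrom == region.chrom and \
                    region.start <= pos < region.end:
                tgt = anti if r.interval.strand == "-" else sense
                tgt[pos - region.start] += 1
    return sense, anti


class TestFilters:
    def test_min_length_23(self):
        records = [make_record(i, "l", 0, L, "+") for i, L in
                   enumerate((22, 23, 30))]
        kept = filter_pirna_alignments(records, 23)
        assert sorted(r.read_length for r in kept) == [23, 30]

    def test_pingpong_window_excludes_33mers(self):
        records = [make_record(i, "l", 0, L, "+") for i, L in
                   enumerate((23, 32, 33))]
        kept = filter_pirna_alignments(records, 23, 32)
        assert sorted(r.read_length for r in kept) == [23, 32]

    def test_empty_input(self):
        assert filter_pirna_alignments([], 23) == []

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            filter_pirna_alignments([], 32, 23)


class TestStrandedCoverage:
    def test_single_plus_read(self):
        region = GenomicInterval("l", 0, 100)
        sense, anti = stranded_coverage([make_record(0, "l", 10, 26, "+")],
                                        region)
        assert sense[10:36].sum() == 26 and sense.sum() == 26
        assert anti.sum() == 0

    def test_read_clipped_to_region(self):
        region = GenomicInterval("l", 20, 50)
        sense, _ = stranded_coverage([make_record(0, "l", 10, 26, "+")],
                                     region)
        assert sense.sum() == 16  # only positions 20..35 counted

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        records = random_records(rng, 100, span=500)
        region = GenomicInterval("locus", 50, 400)
        sense, anti = stranded_coverage(records, region)
        bs, ba = brute_coverage(records, region)
        assert (sense == bs).all() and (anti == ba).all()


class TestPingpong:
    def test_only_exact_overlap_pairs_is_flagged_degenerate(self):
        # every event at the focal position: background sd is 0, z undefined
        records = []
        for k in range(30):
            p = 50 * k + 20
            records.append(make_record(2 * k, "l", p, 26, "+"))
            # minus 5' end at p+9: interval [p+10-28, p+10)
            records.append(make_record(2 * k + 1, "l", p - 18, 28, "-"))
        result = pingpong_zscore(records)
        assert result.frequency_at(10) == 1.0
        assert result.flagged and result.z_score is None

    def test_dominant_overlap_10_gives_large_positive_z(self):
        rng = np.random.default_rng(320)
        records = random_records(rng, 60, span=700)
        for k in range(40):
            p = int(rng.integers(20, 600))
            records.append(make_record(1000 + 2 * k, "l", p, 26, "+"))
            records.append(make_record(1001 + 2 * k, "l", p - 18, 28, "-"))
        result = pingpong_zscore(records)
        assert result.frequency_at(10) == max(result.frequencies)
        assert result.z_score > 4
        brute = brute_pingpong_counts(records)
        np.testing.assert_allclose(result.frequencies, brute / brute.sum(),
                                   atol=1e-12)

    def test_single_strand_input_rejected(self):
        with pytest.raises(ValueError):
            pingpong_zscore([make_record(0, "l", 0, 26, "+"),
                             make_record(1, "l", 40, 26, "+")])

    @pytest.mark.parametrize("seed", range(10))
    def test_histogram_matches_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        records = random_records(rng, int(rng.integers(50, 400)), span=800)
        result = pingpong_zscore(records)
        brute = brute_pingpong_counts(records)
        if brute.sum() == 0:
            assert result.frequencies is None
        else:
            np.testing.assert_allclose(result.frequencies,
                                       brute / brute.sum(), atol=1e-12)

    def test_invariant_under_uniform_duplication(self):
        rng = np.random.default_rng(310)
        records = random_records(rng, 150, span=600)
        base = pingpong_zscore(records)
        doubled = records + [
            AlignmentRecord(r.read_id + "_dup", r.interval, r.read_length)
            for r in records
        ]
        dup = pingpong_zscore(doubled)
        np.testing.assert_allclose(base.frequencies, dup.frequencies,
                                   atol=1e-12)
        assert dup.z_score == pytest.approx(base.z_score)

    def test_z_monotone_in_planted_fraction(self, ltr_element):
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        mean_z = []
        for frac in fractions:
            zs = []
            for seed in range(10):
                records, _ = simulate_small_rna_library(
                    {"e": ltr_element.consensus}, 400,
                    pingpong_fraction=frac, seed=1000 + seed)
                kept = filter_pirna_alignments(records, 23, 32)
                zs.append(pingpong_zscore(kept).z_score)
            mean_z.append(np.mean(zs))
        assert all(a < b for a, b in zip(mean_z, mean_z[1:]))

    def test_uniform_library_null_z_bounded(self, ltr_element):
        inside = 0
        for seed in range(20):
            records, _ = simulate_small_rna_library(
                {"e": ltr_element.consensus}, 500, seed=2000 + seed)
            kept = filter_pirna_alignments(records, 23, 32)
            z = pingpong_zscore(kept).z_score
            if abs(z) < 3:
                inside += 1
        assert inside >= 19


class TestPhasing:
    def test_phased_run_peaks_at_one(self):
        rng = np.random.default_rng(410)
        records = random_records(rng, 40, span=900)
        pos = 100
        for k in range(25):
            records.append(make_record(1000 + k, "l", pos, 26, "+"))
            pos += 26  # next 5' starts exactly at previous end: d = 1
        result = phasing_zscore(records)
        assert result.frequency_at(1) == max(result.frequencies)
        assert result.z_score > 4
        brute = brute_phasing_counts(records)
        np.testing.assert_allclose(result.frequencies, brute / brute.sum(),
                                   atol=1e-12)

    def test_out_of_window_distances_flagged(self):
        records = [make_record(0, "l", 0, 26, "+"),
                   make_record(1, "l", 51, 26, "+")]  # d = 26, no event
        result = phasing_zscore(records)
        assert result.flagged and result.frequencies is None

    @pytest.mark.parametrize("seed", range(10))
    def test_histogram_matches_brute_force(self, seed):
        rng = np.random.default_rng(400 + seed)
        records = random_records(rng, int(rng.integers(50, 400)), span=800)
        result = phasing_zscore(records)
        brute = brute_phasing_counts(records)
        if brute.sum() == 0:
            assert result.frequencies is None
        else:
            np.testing.assert_allclose(result.frequencies,
                                       brute / brute.sum(), atol=1e-12)

    def test_uniform_library_null_z_bounded(self, ltr_element):
        inside = 0
        for seed in range(20):
            records, _ = simulate_small_rna_library(
                {"e": ltr_element.consensus}, 500, seed=3000 + seed)
            kept = filter_pirna_alignments(records, 23)
            z = phasing_zscore(kept).z_score
            if abs(z) < 3:
                inside += 1
        assert inside >= 19

    def test_minus_strand_run_also_phased(self):
        records, pos = [], 1000
        for k in range(15):
            records.append(make_record(k, "l", pos - 26, 26, "-"))
            pos -= 26
        result = phasing_zscore(records)
        assert result.frequency_at(1) == max(result.frequencies)


class TestLengthDistribution:
    def test_all_in_window(self):
        records = [make_record(i, "l", 0, 28, "+") for i in range(5)]
        _, frac = length_distribution(records, (26, 32))
        assert frac == 1.0

    def test_uniform_lengths_fraction(self):
        records = [make_record(i, "l", 0, L, "+")
                   for i, L in enumerate(range(20, 36))]
        _, frac = length_distribution(records, (26, 32))
        assert frac == pytest.approx(7 / 16)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(500)
        records = random_records(rng, 300, lengths=(20, 35))
        hist, frac = length_distribution(records, (26, 32))
        lengths = [r.read_length for r in records]
        assert sum(hist.values()) == 300
        assert frac == sum(1 for l in lengths if 26 <= l <= 32) / 300

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            length_distribution([])
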