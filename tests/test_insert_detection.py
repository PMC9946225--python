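"""Breakend pairing against an exhaustive oracle, size filtering, genotyping
coverage rules, and nested-insertion detection."""

import numpy as np
import pytest

from mobilome_trap.core_io import BreakendRecord, GenomicInterval, LEFT, RIGHT
from mobilome_trap.inserts import (
    detect_nested_insertions,
    evaluate_insert_calls,
    filter_inserts_by_size,
    genotype_insertion_site,
    pair_breakends_to_inserts,
)
from mobilome_trap.synthetic import (
    emit_breakends_from_truth,
    plant_transposon_copies,
    random_element,
    simulate_genome,
    simulate_long_reads,
)


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive all-pairs pairing under the insert rule,
# written from the rule itself (acceptor junctions < max_gap apart with
# opposing flags; donor flags bracketing a positive interval), with the
# documented greedy resolution.
# ---------------------------------------------------------------------------

def oracle_pairing(breakends, max_gap=100):
    candidates = []
    for i in range(len(breakends)):
        for j in range(i + 1, len(breakends)):
            r, s = breakends[i], breakends[j]
            r_ends, s_ends = (r.end_a, r.end_b), (s.end_a, s.end_b)
            best = None
            for ri in (0, 1):
                for si in (0, 1):
                    r_acc, r_don = r_ends[ri], r_ends[1 - ri]
                    s_acc, s_don = s_ends[si], s_ends[1 - si]
                    if r_acc[0] != s_acc[0] or {r_acc[2], s_acc[2]} != {LEFT,
                                                                        RIGHT}:
                        continue
                    gap = abs(r_acc[1] - s_acc[1])
                    if gap >= max_gap:
                        continue
                    if r_don[0] != s_don[0]:
                        continue
                    lo, hi = sorted((r_don, s_don), key=lambda e: e[1])
                    if lo[2] != LEFT or hi[2] != RIGHT or hi[1] <= lo[1]:
                        continue
                    key = (gap, hi[1] - lo[1],
                           r_acc[0], min(r_acc[1], s_acc[1]), lo[0], lo[1])
                    if best is None or key < best:
                        best = key
            if best is not None:
                candidates.append((best, i, j))
    candidates.sort()
    used, pairs = set(), []
    for key, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((key[2], key[3], key[4], key[5], key[1]))  # acc + donor
    return sorted(pairs)


def calls_as_tuples(calls):
    return sorted((c.anchor.chrom, c.anchor.start, c.donor.chrom,
                   c.donor.start, c.length) for c in calls)


def random_breakends(rng, n):
    """Random records concentrated enough to create pairing competition."""
    sides = (LEFT, RIGHT)
    out = []
    for _ in range(n):
        out.append(BreakendRecord(
            f"chr{rng.integers(1, 3)}", int(rng.integers(0, 3000)),
            sides[rng.integers(2)],
            f"chr{rng.integers(1, 3)}", int(rng.integers(0, 30_000)),
            sides[rng.integers(2)]))
    return out


class TestPairing:
    def test_textbook_pair(self):
        b1 = BreakendRecord("chrA", 1000, RIGHT, "chrB", 5000, LEFT)
        b2 = BreakendRecord("chrA", 1040, LEFT, "chrB", 8000, RIGHT)
        calls, residual = pair_breakends_to_inserts([b1, b2])
        assert len(calls) == 1 and not residual
        call = calls[0]
        assert (call.anchor.chrom, call.anchor.start, call.anchor.end) == \
               ("chrA", 1000, 1040)
        assert (call.donor.chrom, call.donor.start, call.donor.end) == \
               ("chrB", 5000, 8000)
        assert call.length == 3000 and call.orientation == "same"

    def test_gap_at_or_above_100_is_no_call(self):
        b1 = BreakendRecord("chrA", 1000, RIGHT, "chrB", 5000, LEFT)
        b2 = BreakendRecord("chrA", 1150, LEFT, "chrB", 8000, RIGHT)
        calls, residual = pair_breakends_to_inserts([b1, b2])
        assert calls == [] and len(residual) == 2
        # strictly less than: a gap of exactly 100 also fails
        b3 = BreakendRecord("chrA", 1100, LEFT, "chrB", 8000, RIGHT)
        calls, _ = pair_breakends_to_inserts([b1, b3])
        assert calls == []
        b4 = BreakendRecord("chrA", 1099, LEFT, "chrB", 8000, RIGHT)
        calls, _ = pair_breakends_to_inserts([b1, b4])
        assert len(calls) == 1

    def test_inverted_orientation_detected(self):
        # acceptor-right junction joined to the donor's high edge
        b1 = BreakendRecord("chrA", 1000, RIGHT, "chrB", 8000, RIGHT)
        b2 = BreakendRecord("chrA", 1010, LEFT, "chrB", 5000, LEFT)
        calls, _ = pair_breakends_to_inserts([b1, b2])
        assert len(calls) == 1 and calls[0].orientation == "inverted"

    def test_order_invariance(self):
        rng = np.random.default_rng(31)
        records = random_breakends(rng, 80)
        calls, _ = pair_breakends_to_inserts(records)
        perm = [records[k] for k in rng.permutation(len(records))]
        calls_perm, _ = pair_breakends_to_inserts(perm)
        assert calls_as_tuples(calls) == calls_as_tuples(calls_perm)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        records = random_breakends(rng, int(rng.integers(50, 200)))
        calls, _ = pair_breakends_to_inserts(records)
        expected = oracle_pairing(records)
        assert calls_as_tuples(calls) == expected

    def test_planted_inserts_recovered_exactly(self, small_genome,
                                               ltr_element):
        _, truth = plant_transposon_copies(small_genome, ltr_element, 8,
                                           seed=41)
        records = emit_breakends_from_truth(truth, 0, 0, seed=42)
        calls, residual = pair_breakends_to_inserts(records)
        assert not residual
        report = evaluate_insert_calls(calls, truth)
        assert report.precision == 1.0 and report.recall == 1.0
        assert calls_as_tuples(calls) == oracle_pairing(records)


class TestSizeFilter:
    def test_inclusive_boundaries(self):
        def call_of(length):
            b1 = BreakendRecord("c", 10, RIGHT, "d", 1000, LEFT)
            b2 = BreakendRecord("c", 10, LEFT, "d", 1000 + length, RIGHT)
            return pair_breakends_to_inserts([b1, b2])[0][0]

        calls = [call_of(l) for l in (50, 100, 9999, 10_000, 10_001)]
        result = filter_inserts_by_size(calls)
        assert sorted(c.length for c in result.kept) == [100, 9999, 10_000]
        assert result.n_below == 1 and result.n_above == 1

    def test_empty_input(self):
        result = filter_inserts_by_size([])
        assert result.kept == [] and result.n_below == result.n_above == 0

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_inserts_by_size([], min_len=500, max_len=100)

    def test_matches_brute_force_on_random_lengths(self):
        rng = np.random.default_rng(55)
        lengths = rng.integers(10, 20_000, size=200)
        calls = []
        for L in lengths:
            b1 = BreakendRecord("c", 10, RIGHT, "d", 1000, LEFT)
            b2 = BreakendRecord("c", 10, LEFT, "d", 1000 + int(L), RIGHT)
            calls.append(pair_breakends_to_inserts([b1, b2])[0][0])
        kept = filter_inserts_by_size(calls).kept
        assert sorted(c.length for c in kept) == \
               sorted(int(l) for l in lengths if 100 <= l <= 10_000)


class TestGenotyping:
    @staticmethod
    def _alleles(seed=61, insert_len=1500, flank_len=1000):
        genome = simulate_genome(1, 10_000, 0.5, seed=seed)["chr1"]
        left = genome[:flank_len]
        right = genome[flank_len:2 * flank_len]
        insert = simulate_genome(1, 10_000, 0.5, seed=seed + 1)["chr1"][:insert_len]
        return left + insert + right, left + right, flank_len

    def test_pure_with_reads_give_ratio_one(self):
        allele_with, allele_without, junction = self._alleles()
        reads, _ = simulate_long_reads(
            {"w": {"s": allele_with}}, mean_len=3000, len_sd=1,
            error_rate=0.0, depth=10 * 3000 / len(allele_with), seed=62)
        call = genotype_insertion_site(reads, allele_with, allele_without,
                                       junction)
        assert call.n_without == 0 and call.n_with > 0 and call.ratio == 1.0

    def test_99bp_flank_not_counted(self):
        allele_with, allele_without, junction = self._alleles()
        # read ends 99 bp after the junction on the empty allele
        read = allele_without[junction - 400:junction + 99]
        call = genotype_insertion_site({"r": read}, allele_with,
                                       allele_without, junction)
        assert call.n_with == 0 and call.n_without == 0 and call.undefined

    def test_100bp_flank_counted(self):
        allele_with, allele_without, junction = self._alleles()
        read = allele_without[junction - 400:junction + 100]
        call = genotype_insertion_site({"r": read}, allele_with,
                                       allele_without, junction)
        assert call.n_without == 1

    def test_mixture_ratio_binomial(self):
        allele_with, allele_without, junction = self._alleles()
        n_with, n_without = 60, 140  # 30/70 mixture
        reads = {}
        reads_w, _ = simulate_long_reads(
            {"w": {"s": allele_with}}, 3000, 1, 0.02,
            depth=n_with * 3000 / len(allele_with), seed=63)
        reads_o, _ = simulate_long_reads(
            {"o": {"s": allele_without}}, 2000, 1, 0.02,
            depth=n_without * 2000 / len(allele_without), seed=64)
        reads.update({f"w{k}": v for k, v in reads_w.items()})
        reads.update({f"o{k}": v for k, v in reads_o.items()})
        call = genotype_insertion_site(reads, allele_with, allele_without,
                                       junction)
        n = call.n_with + call.n_without
        assert n >= 150  # nearly all reads span the junction window
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(call.ratio - 0.3) < 3 * sd + 0.02

    def test_short_alleles_rejected(self):
        with pytest.raises(ValueError):
            genotype_insertion_site({}, "A" * 150, "A" * 100, 50, flank=100)


class TestNestedInsertions:
    focal = [GenomicInterval("chr1", 10_000, 16_000)]
    lengths = {"tnB": 4000}

    def test_terminus_inside_focal_reported(self):
        bnd = BreakendRecord("tnB", 30, LEFT, "chr1", 12_000, RIGHT)
        found = detect_nested_insertions([bnd], self.focal, self.lengths)
        assert len(found) == 1
        hit = found[0]
        assert hit.element == "tnB" and hit.terminus == "5p"
        assert hit.offset_in_focal == 2000

    def test_three_prime_terminus_reported(self):
        bnd = BreakendRecord("tnB", 3950, RIGHT, "chr1", 15_000, LEFT)
        found = detect_nested_insertions([bnd], self.focal, self.lengths)
        assert len(found) == 1 and found[0].terminus == "3p"

    def test_internal_junction_not_reported(self):
        # 150 bp from either terminus: outside the 100 bp tolerance
        bnd = BreakendRecord("tnB", 150, LEFT, "chr1", 12_000, RIGHT)
        assert detect_nested_insertions([bnd], self.focal, self.lengths) == []

    def test_junction_outside_focal_not_reported(self):
        bnd = BreakendRecord("tnB", 30, LEFT, "chr1", 20_000, RIGHT)
        assert detect_nested_insertions([bnd], self.focal, self.lengths) == []

    def test_planted_nested_recovered(self):
        rng = np.random.default_rng(71)
        records, expected = [], 0
        for i in range(20):
            inside = int(rng.integers(10_000, 16_000))
            end_pos = int(rng.integers(0, 4000))
            records.append(BreakendRecord("tnB", end_pos, LEFT,
                                          "chr1", inside, RIGHT))
            if min(end_pos, 3999 - end_pos) <= 100:
                expected += 1
        found = detect_nested_insertions(records, self.focal, self.lengths)
        assert len(found) == expected
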