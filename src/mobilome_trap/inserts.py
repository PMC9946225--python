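"""Novel-insertion calling from breakends, size filtering, genotyping, and
nested-insertion detection.

An insert is called when two breakend junctions fall less than ``max_gap``
(default 100) bp apart at the acceptor locus with orientation flags
consistent with a single inserted donor segment; the region bracketed at the
donor locus is the insert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import BreakendRecord, GenomicInterval, LEFT, RIGHT
from .homology import infix_alignment
from .synthetic import SyntheticTruth


@dataclass(frozen=True)
class InsertCall:
    """A paired-junction insertion event.

    ``anchor`` spans the two acceptor-side junction coordinates (1 bp wide
    when they coincide); ``donor`` is the inserted interval at the donor
    locus; ``length`` is the donor span.
    """

    anchor: GenomicInterval
    donor: GenomicInterval
    orientation: str                 # same | inverted
    length: int
    support: tuple[tuple[str, ...], tuple[str, ...]]

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("insert length must be positive")


@dataclass(frozen=True)
class _Candidate:
    gap: int
    length: int
    i: int
    j: int
    call: InsertCall


def _pair_geometry(r: BreakendRecord, s: BreakendRecord, max_gap: int):
    """Best insert geometry for a breakend pair, or None.

    Tries every assignment of acceptor vs donor ends.  Acceptor: same chrom,
    opposing side flags, junction coordinates < max_gap apart.  Donor: same
    chrom, a left flag at the lower coordinate and a right flag at the
    higher, bracketing a positive-length interval.  Orientation follows from
    which donor edge the acceptor-right junction joins: the low edge means
    the segment was inserted forward, the high edge inverted.
    """
    best = None
    ends_r = (r.end_a, r.end_b)
    ends_s = (s.end_a, s.end_b)
    for ai in (0, 1):
        for aj in (0, 1):
            acc_r, acc_s = ends_r[ai], ends_s[aj]
            don_r, don_s = ends_r[1 - ai], ends_s[1 - aj]
            if acc_r[0] != acc_s[0] or acc_r[2] == acc_s[2]:
                continue
            gap = abs(acc_r[1] - acc_s[1])
            if gap >= max_gap:
                continue
            if don_r[0] != don_s[0]:
                continue
            (lo_chrom, lo_pos, lo_side), (hi_chrom, hi_pos, hi_side) = sorted(
                (don_r, don_s), key=lambda e: e[1])
            if lo_side != LEFT or hi_side != RIGHT or hi_pos <= lo_pos:
                continue
            acc_right = acc_r if acc_r[2] == RIGHT else acc_s
            donor_of_right = don_r if acc_right is acc_r else don_s
            orientation = "same" if donor_of_right[1] == lo_pos else "inverted"
            a_lo = min(acc_r[1], acc_s[1])
            a_hi = max(acc_r[1], acc_s[1])
            call = InsertCall(
                anchor=GenomicInterval(acc_r[0], a_lo, max(a_hi, a_lo + 1)),
                donor=GenomicInterval(lo_chrom, lo_pos, hi_pos),
                orientation=orientation,
                length=hi_pos - lo_pos,
                support=(r.read_ids, s.read_ids),
            )
            key = (gap, call.length)
            if best is None or key < best[:2]:
                best = (gap, call.length, call)
    return best


def pair_breakends_to_inserts(breakends: Sequence[BreakendRecord],
                              max_gap: int = 100):
    """Pair junctions into insert calls; returns (calls, residual breakends).

    When several pairings compete, resolution is greedy by smallest
    acceptor-side gap, then smallest donor span; each breakend participates
    in at most one call.  The result is invariant to input order; calls are
    sorted by acceptor position.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    records = sorted(range(len(breakends)),
                     key=lambda i: (breakends[i].canonical().end_a,
                                    breakends[i].canonical().end_b))
    candidates: list[_Candidate] = []
    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            i, j = records[a], records[b]
            geom = _pair_geometry(breakends[i], breakends[j], max_gap)
            if geom is not None:
                gap, length, call = geom
                candidates.append(_Candidate(gap, length, a, b, call))
    candidates.sort(key=lambda c: (
        c.gap, c.length, c.call.anchor.chrom, c.call.anchor.start,
        c.call.donor.chrom, c.call.donor.start))
    used: set[int] = set()
    calls: list[InsertCall] = []
    for cand in candidates:
        if cand.i in used or cand.j in used:
            continue
        used.update((cand.i, cand.j))
        calls.append(cand.call)
    residual = [breakends[records[k]] for k in range(len(records))
                if k not in used]
    calls.sort(key=lambda c: (c.anchor.chrom, c.anchor.start, c.donor.chrom,
                              c.donor.start))
    return calls, residual


@dataclass
class SizeFilterResult:
    kept: list[InsertCall]
    n_below: int
    n_above: int


def filter_inserts_by_size(calls: Iterable[InsertCall], min_len: int = 100,
                           max_len: int = 10_000) -> SizeFilterResult:
    """Retain calls with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept, below, above = [], 0, 0
    for call in calls:
        if call.length < min_len:
            below += 1
        elif call.length > max_len:
            above += 1
        else:
            kept.append(call)
    return SizeFilterResult(kept, below, above)


# ---------------------------------------------------------------------------
# Genotyping from long reads
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    site: GenomicInterval | None
    n_with: int
    n_without: int

    @property
    def ratio(self) -> float | None:
        total = self.n_with + self.n_without
        if total == 0:
            return None
        return self.n_with / total

    @property
    def undefined(self) -> bool:
        return self.n_with + self.n_without == 0


def genotype_insertion_site(long_reads: Mapping[str, str], allele_with: str,
                            allele_without: str, junction_offset: int,
                            flank: int = 100,
                            site: GenomicInterval | None = None) -> GenotypeCall:
    """Count reads supporting the inserted vs the empty allele.

    A read is informative for an allele when its best placement on that
    allele covers at least ``flank`` bp on both sides of a junction (either
    insertion boundary for the inserted allele) and its alignment score is
    strictly better (lower edit distance) than on the other allele; ties
    count for neither.
    """
    if len(allele_with) < 2 * flank or len(allele_without) < 2 * flank:
        raise ValueError("allele sequences must span at least 2 x flank")
    insert_len = len(allele_with) - len(allele_without)
    if insert_len <= 0:
        raise ValueError("allele_with must be longer than allele_without")
    j_without = junction_offset
    j_with = (junction_offset, junction_offset + insert_len)

    n_with = n_without = 0
    for read in long_reads.values():
        aln_w = infix_alignment(read, allele_with)
        aln_o = infix_alignment(read, allele_without)
        d_w = aln_w[0] if aln_w else None
        d_o = aln_o[0] if aln_o else None
        cov_w = aln_w is not None and any(
            aln_w[1] <= j - flank and aln_w[2] >= j + flank for j in j_with)
        cov_o = aln_o is not None and (
            aln_o[1] <= j_without - flank and aln_o[2] >= j_without + flank)
        if cov_w and (d_o is None or d_w < d_o):
            n_with += 1
        elif cov_o and (d_w is None or d_o < d_w):
            n_without += 1
    return GenotypeCall(site, n_with, n_without)


# ---------------------------------------------------------------------------
# Nested insertions inside a focal element
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedInsertion:
    breakend: BreakendRecord
    element: str                     # donor transposon sequence name
    terminus: str                    # 5p | 3p
    distance_to_terminus: int
    focal: GenomicInterval
    offset_in_focal: int


def detect_nested_insertions(breakends: Sequence[BreakendRecord],
                             focal_elements: Sequence[GenomicInterval],
                             element_lengths: Mapping[str, int],
                             tolerance: int = 100) -> list[NestedInsertion]:
    """Single-end rule: report breakends joining a transposon terminus
    (within ``tolerance`` bp of either end) to a position inside a focal
    element.  One such junction suffices — no pairing required.
    """
    out = []
    for bnd in breakends:
        for inner, outer in ((bnd.end_a, bnd.end_b), (bnd.end_b, bnd.end_a)):
            focal = next((f for f in focal_elements
                          if f.chrom == inner[0]
                          and f.contains_point(inner[1])), None)
            if focal is None:
                continue
            elem_len = element_lengths.get(outer[0])
            if elem_len is None:
                continue
            dist5 = outer[1]
            dist3 = (elem_len - 1) - outer[1]
            dist = min(dist5, dist3)
            if dist > tolerance:
                continue
            out.append(NestedInsertion(
                breakend=bnd, element=outer[0],
                terminus="5p" if dist5 <= dist3 else "3p",
                distance_to_terminus=dist, focal=focal,
                offset_in_focal=inner[1] - focal.start))
            break  # one report per breakend
    return out


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    n_true: int
    n_called: int
    true_positives: int

    @property
    def precision(self) -> float:
        return self.true_positives / self.n_called if self.n_called else 0.0

    @property
    def recall(self) -> float:
        return self.true_positives / self.n_true if self.n_true else 0.0


def evaluate_insert_calls(calls: Sequence[InsertCall], truth: SyntheticTruth,
                          tol: int = 60) -> RecoveryReport:
    """Match calls to planted inserts (anchor within ``tol`` bp of the
    planted acceptor point, donor chromosome agreeing); 1-1 greedy match."""
    unmatched = list(truth.planted_inserts)
    tp = 0
    for call in calls:
        mid = (call.anchor.start + call.anchor.end) // 2
        hit = next(
            (ins for ins in unmatched
             if ins.acceptor.chrom == call.anchor.chrom
             and abs(ins.acceptor.start - mid) <= tol
             and ins.donor.chrom == call.donor.chrom), None)
        if hit is not None:
            unmatched.remove(hit)
            tp += 1
    return RecoveryReport(len(truth.planted_inserts), len(calls), tp)
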