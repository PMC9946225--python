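"""piRNA-defining filters, stranded coverage, and the ping-pong / phasing
signature statistics.

The ping-pong signature counts, over opposite-strand read pairs, the number
of bases by which their 5' ends overlap; reciprocal cleavage puts the peak at
exactly 10 nt.  The phasing signature counts, over same-strand ordered read
pairs, the distance from an upstream 3' end to the next 5' end, with
head-to-tail adjacency defined as distance 1 (an overlap of one base is 0).
Each statistic is summarized by the z-score of the focal position's frequency
against the remaining positions of its window: overlaps 1-20 with background
{1..9, 11..20} for ping-pong, distances 0-19 with background {0, 2..19} for
phasing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import AlignmentRecord, GenomicInterval

PINGPONG_POSITIONS = tuple(range(1, 21))
PINGPONG_FOCAL = 10
PHASING_POSITIONS = tuple(range(0, 20))
PHASING_FOCAL = 1


@dataclass
class SignatureResult:
    kind: str                        # pingpong | phasing
    positions: tuple[int, ...]
    frequencies: np.ndarray | None   # None when no events fell in the window
    focal_position: int
    background_positions: tuple[int, ...]
    z_score: float | None
    flagged: bool                    # True when z is undefined

    def frequency_at(self, position: int) -> float:
        if self.frequencies is None:
            raise ValueError("no events in the signature window")
        return float(self.frequencies[self.positions.index(position)])


def filter_pirna_alignments(records: Iterable[AlignmentRecord],
                            min_len: int = 23,
                            max_len: int | None = None) -> list[AlignmentRecord]:
    """Length gate for piRNA analyses (>= 23 nt; 23-32 for ping-pong input)."""
    if max_len is not None and min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [r for r in records
            if r.read_length >= min_len
            and (max_len is None or r.read_length <= max_len)]


def stranded_coverage(records: Iterable[AlignmentRecord],
                      region: GenomicInterval):
    """Per-nucleotide coverage over ``region``, sense and antisense.

    Every mapped placement counts once; reads are clipped to the region.
    Returns (sense, antisense) as nonnegative integer vectors of the region
    span.  For display the antisense track is conventionally negated.
    """
    span = len(region)
    sense = np.zeros(span, dtype=np.int64)
    antisense = np.zeros(span, dtype=np.int64)
    for rec in records:
        iv = rec.interval
        if iv.chrom != region.chrom:
            continue
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start
        if lo >= hi:
            continue
        (antisense if iv.strand == "-" else sense)[lo:hi] += 1
    return sense, antisense


def _collapse_species(records: Sequence[AlignmentRecord]):
    """Unique (chrom, start, end, strand) species with copy-number weights.

    Pair weighting multiplies species weights, which equals counting every
    placement pair once and makes the frequencies invariant under uniform
    duplication of the library.
    """
    counter: Counter = Counter()
    for rec in records:
        iv = rec.interval
        counter[(iv.chrom, iv.start, iv.end, iv.strand)] += 1
    return counter


def _zscore(freqs: np.ndarray, positions: tuple[int, ...], focal: int,
            background: tuple[int, ...]):
    bg = np.array([freqs[positions.index(p)] for p in background], dtype=float)
    sd = float(np.std(bg, ddof=1))
    if sd == 0.0:
        return None, True
    z = (float(freqs[positions.index(focal)]) - float(np.mean(bg))) / sd
    return z, False


def _result(kind, positions, focal, background, counts: np.ndarray):
    total = counts.sum()
    if total == 0:
        return SignatureResult(kind, positions, None, focal, background,
                               None, True)
    freqs = counts / total
    z, flagged = _zscore(freqs, positions, focal, background)
    return SignatureResult(kind, positions, freqs, focal, background, z, flagged)


def pingpong_zscore(records: Sequence[AlignmentRecord]) -> SignatureResult:
    """Ping-pong signature over 5'-5' overlaps of opposite-strand pairs.

    The overlap of a (+, -) placement pair is the inclusive span from the
    plus 5' end to the minus 5' end; overlaps of 1-20 are accumulated with
    species-pair weights, frequencies normalized over the window, and the
    z-score taken at overlap 10.  Input is expected pre-filtered to the
    23-32 nt ping-pong window.
    """
    species = _collapse_species(records)
    plus = [(k, w) for k, w in species.items() if k[3] == "+"]
    minus = [(k, w) for k, w in species.items() if k[3] == "-"]
    if not plus or not minus:
        raise ValueError("ping-pong signature needs reads on both strands")
    counts = np.zeros(len(PINGPONG_POSITIONS), dtype=float)
    minus_by_chrom: dict[str, list] = {}
    for k, w in minus:
        minus_by_chrom.setdefault(k[0], []).append((k, w))
    for (chrom, p_start, _p_end, _), w_p in plus:
        for (_, m_start, m_end, _), w_m in minus_by_chrom.get(chrom, ()):  #
            overlap = (m_end - 1) - p_start + 1  # inclusive 5'..5' span
            if 1 <= overlap <= 20:
                counts[overlap - 1] += w_p * w_m
    return _result("pingpong", PINGPONG_POSITIONS, PINGPONG_FOCAL,
                   tuple(p for p in PINGPONG_POSITIONS if p != PINGPONG_FOCAL),
                   counts)


def phasing_zscore(records: Sequence[AlignmentRecord]) -> SignatureResult:
    """Phasing signature over same-strand 3'-to-next-5' distances.

    For ordered same-strand pairs, d = downstream 5' start - upstream 3' end
    (in transcription direction) + 1, so head-to-tail adjacency scores d = 1
    and a one-base overlap d = 0.  Distances 0-19 are accumulated with
    species-pair weights; the z-score is taken at d = 1.  Input is expected
    pre-filtered to >= 23 nt.
    """
    species = _collapse_species(records)
    by_strand: dict[str, dict[str, list]] = {"+": {}, "-": {}}
    for (chrom, start, end, strand), w in species.items():
        if strand in by_strand:
            by_strand[strand].setdefault(chrom, []).append((start, end, w))
    if not any(by_strand["+"].values()) and not any(by_strand["-"].values()):
        raise ValueError("phasing signature needs mapped reads")
    counts = np.zeros(len(PHASING_POSITIONS), dtype=float)
    for strand, per_chrom in by_strand.items():
        for chrom, items in per_chrom.items():
            for (s1, e1, w1) in items:
                for (s2, e2, w2) in items:
                    if (s1, e1) == (s2, e2):
                        continue
                    if strand == "+":
                        d = s2 - e1 + 1
                    else:
                        d = s1 - e2 + 1
                    if 0 <= d <= 19:
                        counts[d] += w1 * w2
    return _result("phasing", PHASING_POSITIONS, PHASING_FOCAL,
                   tuple(p for p in PHASING_POSITIONS if p != PHASING_FOCAL),
                   counts)


def length_distribution(records: Sequence[AlignmentRecord],
                        window: tuple[int, int] | None = None):
    """Histogram of read lengths and, optionally, the fraction in a window.

    Returns (Counter, fraction) where fraction is None without a window.
    """
    if not records:
        raise ValueError("no records for length distribution")
    hist = Counter(r.read_length for r in records)
    fraction = None
    if window is not None:
        lo, hi = window
        total = sum(hist.values())
        fraction = sum(c for l, c in hist.items() if lo <= l <= hi) / total
    return hist, fraction
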