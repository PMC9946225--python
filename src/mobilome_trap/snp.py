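"""SNP sites across near-identical element copies and the allele composition
of small-RNA/mRNA reads at those sites.

Copies of an actively expanding element differ by a handful of
substitutions.  Aligning every copy to one reference copy projects them onto
a common coordinate system; columns where at least two copies disagree (and
none has a gap) are SNP sites.  Reads mapped to the single reference copy
then vote, at each site they overlap, for the allele their sequence carries —
stratified by strand and library — revealing whether reads derive from one
or from many copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AlignmentRecord
from .homology import global_alignment

_NUCS = ("A", "C", "G", "T")


@dataclass
class CopyAlignment:
    """Per-copy rows projected onto reference-copy coordinates.

    ``rows[copy_id][i]`` is the base the copy aligns to reference position
    ``i`` ('-' where the copy has a deletion).  Insertions relative to the
    reference have no reference coordinate and are dropped from the
    projection (they can never be substitution SNP sites).
    """

    reference_id: str
    rows: dict[str, str]

    @property
    def length(self) -> int:
        return len(self.rows[self.reference_id])


def align_copies(copies: Mapping[str, str], reference_copy_id: str,
                 min_identity: float = 0.90) -> CopyAlignment:
    """Globally align each copy to the reference copy.

    Raises when any copy falls below ``min_identity`` to the reference —
    outside the near-identical regime this method assumes.
    """
    if reference_copy_id not in copies:
        raise ValueError(f"unknown reference copy {reference_copy_id!r}")
    ref = copies[reference_copy_id]
    rows: dict[str, str] = {reference_copy_id: ref}
    for cid, seq in copies.items():
        if cid == reference_copy_id:
            continue
        gapped_copy, gapped_ref, dist = global_alignment(seq, ref)
        identity = 1 - dist / max(len(seq), len(ref))
        if identity < min_identity:
            raise ValueError(
                f"copy {cid!r} identity {identity:.3f} below {min_identity}")
        if len(seq) == len(ref):
            # equal-length copies: when the ungapped alignment is also
            # optimal, prefer it — substitutions stay substitution columns
            # instead of cost-tied indel pairs
            hamming = sum(a != b for a, b in zip(seq, ref))
            if hamming == dist:
                rows[cid] = seq
                continue
        projected = [
            c for c, r in zip(gapped_copy, gapped_ref) if r != "-"
        ]
        rows[cid] = "".join(projected)
    return CopyAlignment(reference_copy_id, rows)


@dataclass(frozen=True)
class SNPSite:
    column: int                      # position in the projected alignment
    ref_position: int                # offset in the reference copy (== column)
    alleles: tuple[tuple[str, str], ...]   # (copy_id, nucleotide)

    def allele_of(self, copy_id: str) -> str:
        return dict(self.alleles)[copy_id]


def call_snp_sites(alignment: CopyAlignment) -> list[SNPSite]:
    """Columns with >= 2 distinct nucleotides and no gap in any copy."""
    ids = sorted(alignment.rows)
    sites = []
    for col in range(alignment.length):
        column = {cid: alignment.rows[cid][col] for cid in ids}
        bases = set(column.values())
        if "-" in bases or not bases <= set(_NUCS):
            continue
        if len(bases) >= 2:
            sites.append(SNPSite(col, col, tuple(sorted(column.items()))))
    return sites


@dataclass(frozen=True)
class ReadTile:
    tile_id: str
    parent_id: str
    offset: int
    sequence: str


def tile_reads(sequences: Mapping[str, str], window: int = 33) -> list[ReadTile]:
    """Split long sequences into consecutive non-overlapping windows.

    The terminal remainder shorter than ``window`` is discarded; provenance
    (parent read, offset) is retained on every tile.
    """
    if window < 20:
        raise ValueError("window must be >= 20")
    tiles = []
    for rid, seq in sequences.items():
        for k in range(len(seq) // window):
            off = k * window
            tiles.append(ReadTile(f"{rid}.{k}", rid, off,
                                  seq[off:off + window]))
    return tiles


def _count_mismatches(rec: AlignmentRecord, reference: str) -> int:
    iv = rec.interval
    n = 0
    for pos in range(max(0, iv.start), min(len(reference), iv.end)):
        base = rec.base_at(pos)
        if base is not None and base != "N" and base != reference[pos]:
            n += 1
    return n


def allele_composition(records_by_library: Mapping[str, Sequence[AlignmentRecord]],
                       reference_copy: str, snp_sites: Sequence[SNPSite],
                       max_mismatches: int = 2,
                       per_placement: bool = False) -> pd.DataFrame:
    """Per-SNP-site nucleotide counts of reads, by strand and library.

    Reads with more than ``max_mismatches`` substitutions against the
    reference copy are excluded entirely.  By default each read contributes
    once, at its best placement (fewest mismatches); ``per_placement`` counts
    every placement.  Antisense reads are complement-corrected so the table
    is in reference-copy sense space; a read with N at a site is excluded
    from that site only.

    Returns a tidy DataFrame indexed by (site, strand, library) with columns
    A, C, G, T and coverage.
    """
    for site in snp_sites:
        if not (0 <= site.ref_position < len(reference_copy)):
            raise ValueError(f"SNP site {site.ref_position} outside reference")

    rows: dict[tuple[int, str, str], dict[str, int]] = {}

    def bucket(site_pos, strand, lib):
        key = (site_pos, strand, lib)
        if key not in rows:
            rows[key] = {n: 0 for n in _NUCS} | {"coverage": 0}
        return rows[key]

    for lib, records in records_by_library.items():
        usable = []
        for rec in records:
            mm = (_count_mismatches(rec, reference_copy)
                  if rec.sequence is not None else rec.mismatches)
            if mm <= max_mismatches:
                usable.append((mm, rec))
        if not per_placement:
            best: dict[str, tuple[int, AlignmentRecord]] = {}
            for mm, rec in usable:
                prev = best.get(rec.read_id)
                if prev is None or mm < prev[0]:
                    best[rec.read_id] = (mm, rec)
            usable = list(best.values())
        for _mm, rec in usable:
            strand = "antisense" if rec.interval.strand == "-" else "sense"
            for site in snp_sites:
                pos = site.ref_position
                if not rec.interval.contains_point(pos):
                    continue
                b = bucket(pos, strand, lib)
                b["coverage"] += 1
                base = rec.base_at(pos)
                if base in _NUCS:
                    b[base] += 1

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["site", "strand",
                                                           "library"])
    return pd.DataFrame([rows[k] for k in sorted(rows)], index=index,
                        columns=list(_NUCS) + ["coverage"])
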