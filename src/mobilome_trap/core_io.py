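"""Domain types and format I/O with fixed coordinate conventions.

All coordinates are 0-based half-open internally.  Conversion happens only at
format boundaries: VCF breakend positions (1-based) are shifted on ingest and
restored on write; BED passes through unchanged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LEFT = "left"
RIGHT = "right"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T's partner)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped placement of a read.

    Multi-mapped reads appear as several records sharing ``read_id``, each
    carrying ``n_placements``.  ``sequence``, when present, is the read in its
    own 5'->3' orientation (i.e. the reverse complement of the reference for
    '-' strand placements).
    """

    read_id: str
    interval: GenomicInterval
    read_length: int
    mismatches: int = 0
    n_placements: int = 1
    sequence: str | None = None

    def __post_init__(self):
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")
        if self.n_placements < 1:
            raise ValueError("n_placements must be >= 1")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (0-based)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end (0-based)."""
        if self.interval.strand == "-":
            return self.interval.start
        return self.interval.end - 1

    def base_at(self, ref_pos: int) -> str | None:
        """Base this read places at reference position, in reference sense.

        Assumes an ungapped placement.  Returns None when the read does not
        overlap the position or carries no sequence.
        """
        if self.sequence is None or not self.interval.contains_point(ref_pos):
            return None
        if self.interval.strand == "-":
            idx = self.interval.end - 1 - ref_pos
            base = self.sequence[idx]
            return base.translate(_COMPLEMENT)
        return self.sequence[ref_pos - self.interval.start]


@dataclass(frozen=True)
class BreakendRecord:
    """A junction between two genomic positions, as emitted by an SV caller.

    Positions are 0-based (converted at ingest from 1-based VCF).  ``side``
    states where the junction sits relative to the retained segment at that
    position: 'left' means the segment extends rightward from the position,
    'right' means it extends leftward (the junction is after the base).
    The record is symmetric: swapping the two ends denotes the same junction.
    """

    chrom_a: str
    pos_a: int
    side_a: str
    chrom_b: str
    pos_b: int
    side_b: str
    read_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError("breakend positions must be >= 0")
        if self.side_a not in (LEFT, RIGHT) or self.side_b not in (LEFT, RIGHT):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def end_a(self) -> tuple[str, int, str]:
        return (self.chrom_a, self.pos_a, self.side_a)

    @property
    def end_b(self) -> tuple[str, int, str]:
        return (self.chrom_b, self.pos_b, self.side_b)

    def canonical(self) -> "BreakendRecord":
        """Order-normalized form so the symmetry invariant is testable."""
        if self.end_b < self.end_a:
            return BreakendRecord(
                self.chrom_b, self.pos_b, self.side_b,
                self.chrom_a, self.pos_a, self.side_a,
                self.read_ids,
            )
        return self

    def same_junction(self, other: "BreakendRecord") -> bool:
        a, b = self.canonical(), other.canonical()
        return a.end_a == b.end_a and a.end_b == b.end_b


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: uppercase sequence} map.

    Duplicate identifiers and empty sequences are format errors; IUPAC
    letters are preserved.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicated FASTA identifier {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    """Write BED6 (0-based half-open; strand in column 6)."""
    intervals = list(intervals)
    if names is None:
        names = ["." for _ in intervals]
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            if iv.start < 0:
                raise ValueError("negative coordinate in BED output")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


# ---------------------------------------------------------------------------
# Breakends: VCF 4.2 BND and a BED-like candidates dialect
# ---------------------------------------------------------------------------

_BND_ALT = re.compile(
    r"^(?P<pre>[A-Za-z.]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<post>[A-Za-z.]*)$"
)


def _decode_bnd_alt(chrom: str, pos1: int, alt: str):
    """Decode one VCF 4.2 BND ALT into ((here), (mate)) side flags.

    1-based coordinates in, 1-based out (the caller converts).  The four
    bracket forms map as::

        t[p[  -> here right, mate left          (mate segment extends right)
        t]p]  -> here right, mate right         (inverted join)
        ]p]t  -> here left,  mate right
        [p[t  -> here left,  mate left          (inverted join)
    """
    m = _BND_ALT.match(alt)
    if m is None or m.group("open") != m.group("close"):
        raise FormatError(f"unrecognized BND ALT {alt!r}")
    bracket = m.group("open")
    mate = (m.group("chrom"), int(m.group("pos")))
    if m.group("pre") and not m.group("post"):
        here_side = RIGHT
    elif m.group("post") and not m.group("pre"):
        here_side = LEFT
    else:
        raise FormatError(f"unrecognized BND ALT {alt!r}")
    mate_side = LEFT if bracket == "[" else RIGHT
    return (chrom, pos1, here_side), (mate[0], mate[1], mate_side)


def read_breakends(path, dialect: str = "vcf_bnd") -> list[BreakendRecord]:
    """Read breakend records; see module docstring for conventions.

    ``vcf_bnd`` parses VCF 4.2 BND records (bracket ALT notation); mate pairs
    (MATEID) are collapsed to one BreakendRecord per junction.  Records whose
    ALT cannot be decoded are skipped with a warning.

    ``candidates_bed`` parses a documented 6+1 column TSV dialect::

        chrom_a  pos0_a  side_a  chrom_b  pos0_b  side_b  [read_ids,comma]

    with 0-based positions (BED-like).
    """
    if dialect == "candidates_bed":
        return _read_candidates_bed(path)
    if dialect != "vcf_bnd":
        raise ValueError(f"unknown breakend dialect {dialect!r}")

    records: list[BreakendRecord] = []
    seen: set[tuple] = set()
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: fewer than 8 VCF columns")
            chrom, pos1, _vid, _ref, alt, _qual, _filt, info = fields[:8]
            try:
                here, mate = _decode_bnd_alt(chrom, int(pos1), alt)
            except FormatError:
                n_skipped += 1
                continue
            read_ids: tuple[str, ...] = ()
            for kv in info.split(";"):
                if kv.startswith("READS="):
                    read_ids = tuple(kv[len("READS="):].split(","))
            rec = BreakendRecord(
                here[0], here[1] - 1, here[2],
                mate[0], mate[1] - 1, mate[2],
                read_ids,
            ).canonical()
            key = (rec.end_a, rec.end_b)
            if key in seen:  # the mate line of an already-seen junction
                continue
            seen.add(key)
            records.append(rec)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} undecodable BND record(s) in {path}")
    return records


def write_breakends(records: Sequence[BreakendRecord], path,
                    dialect: str = "vcf_bnd") -> None:
    """Write breakends; vcf_bnd emits both mate lines per junction."""
    if dialect == "candidates_bed":
        with open(path, "w") as fh:
            for r in records:
                reads = ",".join(r.read_ids)
                fh.write(f"{r.chrom_a}\t{r.pos_a}\t{r.side_a}\t"
                         f"{r.chrom_b}\t{r.pos_b}\t{r.side_b}\t{reads}\n")
        return
    if dialect != "vcf_bnd":
        raise ValueError(f"unknown breakend dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">\n')
        fh.write('##INFO=<ID=READS,Number=.,Type=String,Description="Support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(records):
            ida, idb = f"bnd_{i}_a", f"bnd_{i}_b"
            fh.write(_format_bnd_line(r.end_a, r.end_b, ida, idb, r.read_ids))
            fh.write(_format_bnd_line(r.end_b, r.end_a, idb, ida, r.read_ids))


def _format_bnd_line(here, mate, vid, mate_id, read_ids) -> str:
    chrom, pos0, side = here
    mchrom, mpos0, mside = mate
    mate_str = f"{mchrom}:{mpos0 + 1}"
    if side == RIGHT:
        alt = f"N[{mate_str}[" if mside == LEFT else f"N]{mate_str}]"
    else:
        alt = f"]{mate_str}]N" if mside == RIGHT else f"[{mate_str}[N"
    info = f"SVTYPE=BND;MATEID={mate_id}"
    if read_ids:
        info += ";READS=" + ",".join(read_ids)
    return f"{chrom}\t{pos0 + 1}\t{vid}\tN\t{alt}\t.\tPASS\t{info}\n"


def _read_candidates_bed(path) -> list[BreakendRecord]:
    records = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 columns")
            try:
                rec = BreakendRecord(
                    fields[0], int(fields[1]), fields[2],
                    fields[3], int(fields[4]), fields[5],
                    tuple(fields[6].split(",")) if len(fields) > 6 and fields[6] else (),
                )
            except ValueError:
                n_skipped += 1
                continue
            records.append(rec)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} malformed breakend line(s) in {path}")
    return records


# ---------------------------------------------------------------------------
# SAM subset and tabular alignment records
# ---------------------------------------------------------------------------

def read_sam_alignments(path) -> list[AlignmentRecord]:
    """Read ungapped alignment records from a SAM text file.

    Uses only QNAME, FLAG strand bit, RNAME, POS, SEQ length, NM and NH tags
    (full CIGAR semantics are never needed for ungapped small-RNA reads).
    A missing NM tag is treated as 0 mismatches with a warning.
    """
    out = []
    missing_nm = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            length = aln.query_length or aln.infer_query_length() or 0
            strand = "-" if aln.is_reverse else "+"
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                nm = 0
                missing_nm += 1
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            seq = aln.query_sequence
            if seq is not None and aln.is_reverse:
                seq = revcomp(seq)  # store in read orientation
            out.append(AlignmentRecord(
                read_id=aln.query_name,
                interval=GenomicInterval(
                    aln.reference_name, aln.reference_start,
                    aln.reference_start + length, strand),
                read_length=length,
                mismatches=int(nm),
                n_placements=int(nh),
                sequence=seq,
            ))
    if missing_nm:
        warnings.warn(f"{missing_nm} SAM record(s) lacked NM; mismatches set to 0")
    return out


def write_sam_alignments(records: Sequence[AlignmentRecord], path,
                         ref_lengths: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        tid = {name: i for i, name in enumerate(ref_lengths)}
        for rec in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.interval.chrom]
            a.reference_start = rec.interval.start
            a.flag = 16 if rec.interval.strand == "-" else 0
            a.mapping_quality = 255
            a.cigarstring = f"{rec.read_length}M"
            seq = rec.sequence
            if seq is not None:
                if rec.interval.strand == "-":
                    seq = revcomp(seq)  # SAM stores reference orientation
                a.query_sequence = seq.replace("U", "T")
            a.set_tag("NM", rec.mismatches)
            a.set_tag("NH", rec.n_placements)
            sam.write(a)


_ALN_COLUMNS = ["read_id", "chrom", "start", "end", "strand",
                "read_length", "mismatches", "n_placements", "sequence"]


def write_alignments_tsv(records: Sequence[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for r in records:
            iv = r.interval
            fh.write("\t".join(map(str, [
                r.read_id, iv.chrom, iv.start, iv.end, iv.strand,
                r.read_length, r.mismatches, r.n_placements,
                r.sequence or ".",
            ])) + "\n")


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ALN_COLUMNS:
            raise FormatError(f"{path}: unexpected alignment TSV header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(AlignmentRecord(
                read_id=f[0],
                interval=GenomicInterval(f[1], int(f[2]), int(f[3]), f[4]),
                read_length=int(f[5]),
                mismatches=int(f[6]),
                n_placements=int(f[7]),
                sequence=None if f[8] == "." else f[8],
            ))
    return out
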