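"""Truth-tracked synthetic data: genomes, element expansions, reads, libraries.

Everything here is seeded through :func:`numpy.random.default_rng`; a fixed
seed gives byte-identical output.  Each generator returns, alongside its data,
a truth channel sufficient to compute every downstream stage's expected answer
without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core_io import AlignmentRecord, BreakendRecord, GenomicInterval, LEFT, RIGHT, revcomp

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ATGC", dtype=np.uint8)  # order matches GC weights below


# ---------------------------------------------------------------------------
# Element and truth models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementModel:
    """A transposable-element family used for planting copies.

    LTR elements carry identical ``ltr_length``-bp terminal repeats and
    transpose full length; non-LTR elements produce 5'-truncated copies whose
    retained 3' fraction is drawn from ``truncation_model`` (a (lo, hi)
    uniform range); ITR elements transpose full length.  ``snp_rate`` is the
    per-bp substitution probability distinguishing individual copies.
    """

    name: str
    consensus: str
    element_class: str = "LTR"
    ltr_length: int = 0
    snp_rate: float = 0.0
    truncation_model: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self):
        if self.element_class not in ("LTR", "non_LTR", "ITR"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if not (0.0 <= self.snp_rate <= 0.05):
            raise ValueError("snp_rate must be within [0, 0.05]")
        if self.element_class == "LTR":
            if self.ltr_length <= 0:
                raise ValueError("LTR elements need ltr_length > 0")
            head = self.consensus[: self.ltr_length]
            tail = self.consensus[-self.ltr_length:]
            if head != tail:
                raise ValueError("LTR consensus must begin and end with "
                                 "identical terminal repeats")


@dataclass(frozen=True)
class PlantedInsert:
    element: str
    copy_id: str
    acceptor: GenomicInterval        # reference coords; insertion before acceptor.start
    donor: GenomicInterval           # homologous old-copy region, reference coords
    donor_sequence: str
    zygosity: str                    # het | hom
    haplotypes: tuple[str, ...]      # which haplotypes carry it


@dataclass
class SyntheticTruth:
    """Ground truth for one planted expansion."""

    element: ElementModel
    chrom_lengths: dict[str, int]                  # reference genome (with old copies)
    reference_copies: list[GenomicInterval] = field(default_factory=list)
    planted_inserts: list[PlantedInsert] = field(default_factory=list)
    copy_snps: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    read_provenance: dict[str, tuple[str, str]] = field(default_factory=dict)
    reference_genome: dict[str, str] | None = None


# ---------------------------------------------------------------------------
# Genome and element construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASE_ARR[idx].tobytes().decode()


def simulate_genome(n_chrom: int, chrom_lengths, gc_fraction: float = 0.5,
                    seed: int = 0) -> dict[str, str]:
    """I.i.d. random genome at the given GC; deterministic per seed."""
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    if isinstance(chrom_lengths, int):
        chrom_lengths = [chrom_lengths] * n_chrom
    if len(chrom_lengths) != n_chrom:
        raise ValueError("chrom_lengths must match n_chrom")
    if any(l < 10_000 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": _random_seq(rng, l, gc_fraction)
            for i, l in enumerate(chrom_lengths)}


def random_element(name: str, length: int, element_class: str = "LTR",
                   ltr_length: int = 400, snp_rate: float = 0.005,
                   gc: float = 0.5, seed: int = 0,
                   truncation_model: tuple[float, float] = (0.1, 1.0)) -> ElementModel:
    """Build a random consensus for an element family.

    For the LTR class the consensus is LTR + internal + LTR with identical
    terminal repeats, the structure of a full-length gypsy-type element.
    """
    rng = np.random.default_rng(seed)
    if element_class == "LTR":
        if length <= 2 * ltr_length:
            raise ValueError("length must exceed twice the LTR length")
        ltr = _random_seq(rng, ltr_length, gc)
        internal = _random_seq(rng, length - 2 * ltr_length, gc)
        consensus = ltr + internal + ltr
    else:
        consensus = _random_seq(rng, length, gc)
        ltr_length = 0
    return ElementModel(name, consensus, element_class, ltr_length, snp_rate,
                        truncation_model)


def _mutate(seq: str, rng: np.random.Generator, rate: float):
    """Substitute bases at the given per-bp rate; returns (seq, [(pos, alt)])."""
    if rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    snps = []
    for pos in hits:
        ref = chr(arr[pos])
        others = [b for b in _BASES if b != ref]
        alt = others[rng.integers(len(others))]
        arr[pos] = ord(alt)
        snps.append((int(pos), alt))
    return arr.tobytes().decode(), snps


def _make_copy(element: ElementModel, rng: np.random.Generator):
    """One new copy: (sequence, consensus-offset snps, retained 5' offset)."""
    consensus = element.consensus
    trunc_start = 0
    if element.element_class == "non_LTR":
        lo, hi = element.truncation_model
        frac = rng.uniform(lo, hi)
        trunc_start = int(len(consensus) * (1 - frac))
        trunc_start = min(trunc_start, len(consensus) - 50)
    retained = consensus[trunc_start:]
    seq, local_snps = _mutate(retained, rng, element.snp_rate)
    snps = [(pos + trunc_start, alt) for pos, alt in local_snps]
    return seq, snps, trunc_start


def plant_transposon_copies(genome: Mapping[str, str], element: ElementModel,
                            n_copies: int, zygosity_mix: float = 1.0,
                            seed: int = 0, n_reference_copies: int = 1,
                            min_separation: int = 2000):
    """Plant element copies and return two haplotypes plus the truth channel.

    The base genome first receives ``n_reference_copies`` exact consensus
    copies on both haplotypes — the pre-existing ("old") copies that define
    the donor locus and old genomic area.  Then ``n_copies`` new copies, each
    carrying independent SNPs at the element's ``snp_rate`` (and 5'
    truncation for the non-LTR class), are planted at uniformly sampled
    acceptor sites; ``zygosity_mix`` is the fraction of new copies that are
    heterozygous (present on exactly one haplotype).

    Returns ``({"A": hapA, "B": hapB}, truth)`` where acceptor coordinates in
    the truth are in reference-genome coordinates (after old-copy planting,
    before new insertions).
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome)

    # --- reference (old) copies: spliced into the base genome itself
    reference: dict[str, str] = dict(genome)
    ref_copies: list[GenomicInterval] = []
    for _ in range(n_reference_copies):
        chrom = chroms[rng.integers(len(chroms))]
        L = len(reference[chrom])
        need = len(element.consensus)
        if L < need + 2 * min_separation:
            raise ValueError(f"chromosome {chrom} too short for reference copy")
        pos = int(rng.integers(min_separation, L - min_separation))
        reference[chrom] = reference[chrom][:pos] + element.consensus + reference[chrom][pos:]
        # shift previously placed copies on the same chromosome
        ref_copies = [
            GenomicInterval(iv.chrom, iv.start + need, iv.end + need, iv.strand)
            if iv.chrom == chrom and iv.start >= pos else iv
            for iv in ref_copies
        ]
        ref_copies.append(GenomicInterval(chrom, pos, pos + need, "+"))

    truth = SyntheticTruth(
        element=element,
        chrom_lengths={c: len(s) for c, s in reference.items()},
        reference_copies=sorted(ref_copies),
        reference_genome=dict(reference),
    )

    # --- sample non-overlapping acceptor sites away from old copies
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for iv in ref_copies:
        occupied[iv.chrom].append((iv.start - min_separation, iv.end + min_separation))
    sites: list[tuple[str, int]] = []
    for _ in range(n_copies):
        placed = False
        for _attempt in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            L = len(reference[chrom])
            pos = int(rng.integers(min_separation, L - min_separation))
            if all(not (lo <= pos < hi) for lo, hi in occupied[chrom]):
                occupied[chrom].append((pos - min_separation, pos + min_separation))
                sites.append((chrom, pos))
                placed = True
                break
        if not placed:
            raise ValueError("genome too short to place requested copies "
                             "without overlap")

    donor_ref = truth.reference_copies[0]
    if isinstance(zygosity_mix, (int, float)):
        zygosities = ["het" if rng.random() < zygosity_mix else "hom"
                      for _ in range(n_copies)]
    else:
        zygosities = list(zygosity_mix)

    inserts_by_hap: dict[str, list[tuple[str, int, str]]] = {"A": [], "B": []}
    for i, ((chrom, pos), zyg) in enumerate(zip(sites, zygosities)):
        copy_id = f"{element.name}_copy{i + 1}"
        seq, snps, trunc_start = _make_copy(element, rng)
        if zyg == "het":
            haps = ("A",) if rng.random() < 0.5 else ("B",)
        else:
            haps = ("A", "B")
        donor = GenomicInterval(donor_ref.chrom, donor_ref.start + trunc_start,
                                donor_ref.end, "+")
        truth.planted_inserts.append(PlantedInsert(
            element=element.name, copy_id=copy_id,
            acceptor=GenomicInterval(chrom, pos, pos + 1),
            donor=donor, donor_sequence=seq, zygosity=zyg, haplotypes=haps,
        ))
        truth.copy_snps[copy_id] = snps
        for h in haps:
            inserts_by_hap[h].append((chrom, pos, seq))

    haplotypes = {}
    for hap, ins in inserts_by_hap.items():
        hapseq = dict(reference)
        for chrom in chroms:
            chrom_ins = sorted((p, s) for c, p, s in ins if c == chrom)
            if not chrom_ins:
                continue
            pieces, prev = [], 0
            for p, s in chrom_ins:
                pieces.append(hapseq[chrom][prev:p])
                pieces.append(s)
                prev = p
            pieces.append(hapseq[chrom][prev:])
            hapseq[chrom] = "".join(pieces)
        haplotypes[hap] = hapseq
    return haplotypes, truth


# ---------------------------------------------------------------------------
# Breakends from truth
# ---------------------------------------------------------------------------

def emit_breakends_from_truth(truth: SyntheticTruth, jitter_sd: float = 0.0,
                              fp_rate: float = 0.0, seed: int = 0
                              ) -> list[BreakendRecord]:
    """Two breakends per planted insert, plus Poisson false records.

    Coordinates are perturbed by rounded Gaussian jitter of the given SD;
    ``fp_rate`` is the expected number of spurious breakends per Mb of
    reference genome.  Same-orientation insertions give an acceptor-right
    junction joined to the donor interval's low edge and an acceptor-left
    junction joined to its high edge.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[BreakendRecord] = []

    def jitter(pos: int) -> int:
        if jitter_sd == 0:
            return pos
        return max(0, pos + int(round(rng.normal(0, jitter_sd))))

    for ins in truth.planted_inserts:
        p = ins.acceptor.start
        d0, d1 = ins.donor.start, ins.donor.end
        rid = (f"read_{ins.copy_id}",)
        records.append(BreakendRecord(
            ins.acceptor.chrom, jitter(p), RIGHT,
            ins.donor.chrom, jitter(d0), LEFT, rid))
        records.append(BreakendRecord(
            ins.acceptor.chrom, jitter(p), LEFT,
            ins.donor.chrom, jitter(d1), RIGHT, rid))

    if fp_rate > 0:
        total_mb = sum(truth.chrom_lengths.values()) / 1e6
        n_fp = rng.poisson(fp_rate * total_mb)
        chroms = list(truth.chrom_lengths)
        sides = (LEFT, RIGHT)
        for i in range(n_fp):
            ca = chroms[rng.integers(len(chroms))]
            cb = chroms[rng.integers(len(chroms))]
            records.append(BreakendRecord(
                ca, int(rng.integers(truth.chrom_lengths[ca])),
                sides[rng.integers(2)],
                cb, int(rng.integers(truth.chrom_lengths[cb])),
                sides[rng.integers(2)],
                (f"fp_{i}",)))
    return records


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    haplotype: str
    chrom: str
    start: int
    end: int
    strand: str


def simulate_long_reads(haplotypes, mean_len: int = 10_000, len_sd: float = 1000,
                        error_rate: float = 0.0, depth: float = 10,
                        seed: int = 0):
    """Uniformly sampled long reads with a substitution-only error model.

    ``haplotypes`` maps haplotype name -> {chrom: sequence}; a plain
    {chrom: sequence} mapping is treated as a single haplotype "A".  The read
    count targets ``depth`` x (mean haplotype length) / ``mean_len`` total
    reads, drawn from haplotypes uniformly.  Returns ({read_id: sequence},
    [ReadOrigin...]); minus-strand reads are reverse-complemented.
    """
    if mean_len < 1000:
        raise ValueError("mean_len must be >= 1 kb")
    first = next(iter(haplotypes.values()))
    if isinstance(first, str):
        haplotypes = {"A": haplotypes}
    rng = np.random.default_rng(seed)
    hap_names = list(haplotypes)
    hap_lens = {h: sum(len(s) for s in g.values()) for h, g in haplotypes.items()}
    mean_total = sum(hap_lens.values()) / len(hap_lens)
    n_reads = max(1, int(round(depth * mean_total / mean_len)))

    reads: dict[str, str] = {}
    origins: list[ReadOrigin] = []
    for i in range(n_reads):
        hap = hap_names[rng.integers(len(hap_names))]
        genome = haplotypes[hap]
        chroms = list(genome)
        weights = np.array([len(genome[c]) for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        L = len(genome[chrom])
        rlen = int(np.clip(round(rng.normal(mean_len, len_sd)), 200, L))
        start = int(rng.integers(0, L - rlen + 1))
        seq = genome[chrom][start:start + rlen]
        if error_rate > 0:
            seq, _ = _mutate(seq, rng, error_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"lr_{i}"
        reads[rid] = seq
        origins.append(ReadOrigin(rid, hap, chrom, start, start + rlen, strand))
    return reads, origins


# ---------------------------------------------------------------------------
# Small-RNA libraries
# ---------------------------------------------------------------------------

def _default_length_weights() -> dict[int, float]:
    # ~73% of mass inside the 26-32 nt mode, matching the piRNA length profile
    return {l: (2.32 if 26 <= l <= 32 else 1.0) for l in range(23, 36)}


def simulate_small_rna_library(loci: Mapping[str, str], n_reads: int,
                               pingpong_fraction: float = 0.0,
                               phasing_fraction: float = 0.0,
                               first_u_bias: float = 0.0,
                               tenth_a_bias: float = 0.0,
                               length_weights: Mapping[int, float] | None = None,
                               seed: int = 0):
    """Small-RNA library with configurable ping-pong and phasing structure.

    Ping-pong pairs are opposite-strand reads whose 5' ends overlap by
    exactly 10 nt; phased reads are same-strand head-to-tail runs (each 5'
    end one position after the previous 3' end).  The remaining reads are
    uniform background.  Read lengths are drawn from ``length_weights``
    (default 23-35 nt with the mode spanning 26-32).  Sequence-level 1U/10A
    biases overwrite the corresponding read bases with probability given.

    Returns (records, truth) where truth maps read_id -> generative class in
    {"pingpong", "phased", "background"}.
    """
    if not (0 <= pingpong_fraction <= 1 and 0 <= phasing_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if pingpong_fraction + phasing_fraction > 1 + 1e-9:
        raise ValueError("pingpong_fraction + phasing_fraction must be <= 1")
    weights = dict(length_weights or _default_length_weights())
    lengths = np.array(sorted(weights))
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    max_len = int(lengths.max())
    for name, seq in loci.items():
        if len(seq) < max_len:
            raise ValueError(f"locus {name!r} shorter than the maximum read length")

    rng = np.random.default_rng(seed)
    locus_names = list(loci)
    locus_w = np.array([len(loci[c]) for c in locus_names], dtype=float)
    locus_w /= locus_w.sum()

    def pick_locus() -> str:
        return locus_names[rng.choice(len(locus_names), p=locus_w)]

    def draw_len() -> int:
        return int(lengths[rng.choice(len(lengths), p=probs)])

    n_pp = 2 * int(round(n_reads * pingpong_fraction / 2))
    n_ph = int(round(n_reads * phasing_fraction))
    n_ph = min(n_ph, n_reads - n_pp)
    n_bg = n_reads - n_pp - n_ph

    placements: list[tuple[str, int, int, str, str]] = []  # locus,start,end,strand,class

    for _ in range(n_pp // 2):
        chrom = pick_locus()
        L = len(loci[chrom])
        l_plus, l_minus = draw_len(), draw_len()
        # + read [p, p+l_plus); - read 5' at p+9, interval [p+10-l_minus, p+10)
        lo = max(0, l_minus - 10)
        p = int(rng.integers(lo, L - l_plus + 1))
        placements.append((chrom, p, p + l_plus, "+", "pingpong"))
        placements.append((chrom, p + 10 - l_minus, p + 10, "-", "pingpong"))

    remaining = n_ph
    while remaining > 0:
        chrom = pick_locus()
        L = len(loci[chrom])
        run = min(int(rng.integers(2, 7)), remaining)
        run_lens = [draw_len() for _ in range(run)]
        total = sum(run_lens)
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, L - total + 1))
        if strand == "+":
            pos = start
            for rl in run_lens:
                placements.append((chrom, pos, pos + rl, "+", "phased"))
                pos += rl
        else:
            pos = start + total
            for rl in run_lens:  # transcript order right-to-left
                placements.append((chrom, pos - rl, pos, "-", "phased"))
                pos -= rl
        remaining -= run

    for _ in range(n_bg):
        chrom = pick_locus()
        L = len(loci[chrom])
        rl = draw_len()
        start = int(rng.integers(0, L - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((chrom, start, start + rl, strand, "background"))

    records: list[AlignmentRecord] = []
    truth: dict[str, str] = {}
    for i, (chrom, start, end, strand, cls) in enumerate(placements):
        seq = loci[chrom][start:end]
        if strand == "-":
            seq = revcomp(seq)
        bases = list(seq)
        if first_u_bias and rng.random() < first_u_bias:
            bases[0] = "T"
        if tenth_a_bias and len(bases) >= 10 and rng.random() < tenth_a_bias:
            bases[9] = "A"
        seq = "".join(bases)
        rid = f"sr_{i}"
        records.append(AlignmentRecord(
            read_id=rid,
            interval=GenomicInterval(chrom, start, end, strand),
            read_length=end - start,
            sequence=seq,
        ))
        truth[rid] = cls
    return records, truth


# ---------------------------------------------------------------------------
# Expression / ChIP count tracks
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExpression:
    counts: "object"                  # pandas DataFrame, features x libraries
    chip_counts: "object | None"      # pandas Series per feature
    control_counts: "object | None"


def simulate_expression_tracks(feature_lengths: Mapping[str, int],
                               rpkm_targets: Mapping[str, Mapping[str, float]],
                               library_sizes: Mapping[str, int],
                               chip_enrichment: Mapping[str, float] | None = None,
                               chip_library_size: int = 1_000_000,
                               control_library_size: int = 1_000_000,
                               chip_control_rpkm: float = 10.0,
                               seed: int = 0) -> SimulatedExpression:
    """Poisson count tables at programmed RPKM targets and ChIP enrichments.

    Expected count = rpkm x feature_kb x library_size / 1e6.  ChIP counts are
    Poisson at ``chip_enrichment`` x the control rate, with the control at a
    flat ``chip_control_rpkm``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    features = list(feature_lengths)
    kb = pd.Series({f: feature_lengths[f] / 1000 for f in features})
    counts = {}
    for lib, targets in rpkm_targets.items():
        if lib not in library_sizes:
            raise ValueError(f"no library size for {lib!r}")
        rate = np.array([
            float(targets[f]) * kb[f] * library_sizes[lib] / 1e6 for f in features
        ])
        if (rate < 0).any():
            raise ValueError("rpkm targets must be >= 0")
        counts[lib] = rng.poisson(rate)
    counts_df = pd.DataFrame(counts, index=features)

    chip = control = None
    if chip_enrichment is not None:
        base = np.array([chip_control_rpkm * kb[f] for f in features])
        control = pd.Series(
            rng.poisson(base * control_library_size / 1e6), index=features)
        enr = np.array([float(chip_enrichment[f]) for f in features])
        chip = pd.Series(
            rng.poisson(enr * base * chip_library_size / 1e6), index=features)
    return SimulatedExpression(counts_df, chip, control)
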