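# Methods

This note records the models, conventions and numerical choices behind
`mobilome-trap`, in the order the pipeline runs them.

## Coordinates and formats

All coordinates are 0-based half-open internally; conversion happens only at
format boundaries (VCF positions are shifted by one on ingest and restored on
write, BED passes through). Breakend records are symmetric — swapping the two
ends denotes the same junction — and each end carries a side flag: `left`
means the retained segment extends rightward from the position, `right`
means the junction sits after the base. The four VCF 4.2 bracket forms map
onto these flags deterministically (`t[p[` → here right / mate left, and so
on). SAM input is read through pysam but only the fields an ungapped
small-RNA record needs (QNAME, FLAG strand bit, RNAME, POS, sequence length,
NM, NH); a missing NM tag is treated as zero mismatches with a warning.
The `candidates_bed` breakend dialect is a documented 6+1-column TSV
(`chrom_a pos0_a side_a chrom_b pos0_b side_b [read_ids]`) because the
upstream callers' own breakend BED layout varies between versions.

## Insert calling

Two breakends form an insert call when (a) one end of each lies on the same
acceptor chromosome, strictly less than `max_gap` (default 100) bp apart,
with opposing side flags; and (b) the other two ends share a donor
chromosome with a `left` flag at the lower coordinate and a `right` flag at
the higher, bracketing a positive interval. Deriving the four VCF bracket
cases shows this low-left/high-right pattern holds for a contiguous inserted
segment in *both* orientations; what distinguishes them is which donor edge
the acceptor-`right` junction joins (low edge → forward, high edge →
inverted). When several pairings compete, resolution is greedy by smallest
acceptor gap, then smallest donor span, with deterministic positional
tie-breaks; each breakend is used at most once and unpairable records are
returned as a residual list, not an error. The result is invariant to input
order. Size filtering retains lengths in the inclusive interval
[100, 10000] bp by default — inclusive because the transposon-scale range is
stated as an order-of-magnitude band, and inclusive bounds are the least
surprising reading; the gap threshold itself is strict (< 100).

## Homology search and grouping

The built-in aligner is seed-and-extend: shared 11-mers seed ungapped
X-drop extensions (match +1, mismatch −2, X-drop 40), merged per diagonal,
scored on both strands, with significance from the Karlin–Altschul formula
E = K·m·n·e^(−λS) at K = 0.28, λ = 1.07 (computed in log space so
kilobase-scale scores do not underflow). Gapped extension is deliberately
omitted: the regime this pipeline addresses is near-identical repeat copies
differing by substitutions, and every decision the threshold guards —
identity vs unrelated random sequence — is unambiguous ungapped at
E < 1e-100. The searcher is a pluggable seam; any callable with the same
signature (for example an external search tool adapter) can replace it
without touching downstream stages. No minimum alignment length is imposed
beyond the E-value threshold.

Grouping takes the undirected graph whose edges are significant hits in
either direction and returns connected components, so locally homologous
sequences bridged by a longer insert land in one group. Groups are numbered
by descending member count (ties by smallest member id); groups with ≥ 5
members are flagged as focus groups. The representative is the longest
member (ties by smallest id). For the activity ratio, `old_area` is the
union of genomic intervals the representative hits at the threshold (merged
across overlaps, because they are *regions* of the genome) while `new_area`
is the plain sum of member insert lengths (distinct sequences, not genome
intervals); the ratio is flagged infinite, not numeric, when `old_area` is
zero.

## piRNA signatures

Reads ≥ 23 nt count as piRNAs; ping-pong input is further restricted to
23–32 nt. Placements are collapsed to unique (position, length, strand)
species whose copy numbers multiply as pair weights — exactly equivalent to
enumerating every placement pair once, which makes the histogram invariant
under uniform duplication of the library and lets a quadratic brute-force
pair scan serve as the oracle in tests. Multi-mapped placements all
contribute.

Ping-pong: for every (+, −) pair the overlap is the inclusive span from the
plus 5′ end to the minus 5′ end; overlaps 1–20 are tallied, frequencies
normalized over that window, and the z-score taken at 10 against the other
nineteen positions. Phasing: for every ordered same-strand pair, the
distance is downstream-5′ minus upstream-3′ (in transcription direction)
plus one, so head-to-tail adjacency scores 1 and a one-base overlap 0;
distances 0–19 are tallied with the z-score at 1 against {0, 2–19}. The
z-score divides the focal frequency's difference from the background mean by
the background standard deviation; the sample deviation (ddof = 1) is used.
When no events fall in the window, or the background deviation is zero (for
instance a library consisting solely of exact focal pairs), the result is
flagged undefined rather than propagating a NaN or an artificial infinity.
Stranded per-nucleotide coverage counts every placement once, clipped to the
region; antisense values are negated only for display.

## SNP assignment

Copies are globally aligned to one reference copy (edit-distance alignment
via edlib) and projected onto reference coordinates; insertions relative to
the reference have no reference coordinate and are dropped — they can never
be substitution sites. For equal-length copies whose Hamming distance equals
their edit distance, the ungapped alignment is itself optimal and is used
directly, so cost-tied indel representations of adjacent substitutions never
hide a variant column. Copies below 90% identity are rejected: the method
assumes the near-identical regime. A column is a SNP site iff at least two
distinct nucleotides appear and no copy has a gap there. Long reads are
tiled into consecutive non-overlapping 33-nt windows (terminal remainder
dropped, provenance kept). Composition counting excludes reads with more
than 2 substitutions against the reference copy entirely, counts each read
once at its best placement by default (a flag switches to per-placement),
complement-corrects antisense reads into reference sense space, and drops a
read from an individual site only when it carries N there.

## Genotyping

Both allele models (with and without the insertion) are built around the
same junction. A read supports an allele when its best semi-global placement
(tried in both orientations) covers at least 100 bp on both sides of a
junction — either insertion boundary on the inserted allele — *and* its edit
distance there is strictly lower than on the other allele; ties support
neither. The call reports supporting counts and their ratio, undefined
(flagged) when no read qualifies.

## Expression and chromatin

RPKM = count / (feature kb × library millions). Relative expression divides
by the baseline (day 0) library per feature; a zero baseline flags the value
as undefined rather than infinite. The expressed-element filter is a strict
`rpkm > 10` in at least one named library. ChIP enrichment is
log2(chip RPKM / control RPKM) per feature; group summaries pool
length-corrected counts over members before forming the ratio (robust to
zero-count members), with a flag to switch to the mean of per-member ratios.
Split gene models can be merged (summed counts, summed lengths) before RPKM
through a merge table.

## Synthetic data

The generator provides every input with a complete truth channel, so each
downstream stage's expected answer is computable from truth alone.

* **Genome**: i.i.d. bases at a configurable GC fraction (chromosomes
  ≥ 10 kb).
* **Element families**: LTR elements carry identical terminal repeats and
  transpose full length; non-LTR copies are 5′-truncated with a uniform
  retained-3′-fraction model; per-copy substitutions at `snp_rate` ≤ 0.05
  per bp (pipeline default 0.003, a realistic recent-expansion divergence).
  Pre-existing ("old") consensus copies are planted first and define the
  donor locus and old area; new copies are heterozygous by default (present
  on one of two haplotypes), matching how recent insertions segregate.
* **Breakends**: two per planted insert (acceptor-right↔donor-low,
  acceptor-left↔donor-high), Gaussian coordinate jitter, Poisson false
  records per Mb.
* **Long reads**: uniform sampling from both haplotypes, Gaussian lengths,
  substitution-only errors. Indels are deliberately not simulated — junction
  pairing and allele-voting logic are exercised without CIGAR complexity.
  Target-site duplications are likewise not simulated; the ≤ 100 bp junction
  tolerance of the caller subsumes TSD-scale offsets.
* **Small RNA**: ping-pong pairs are opposite-strand reads with exactly
  10-nt 5′ overlap (initiating strand a fair coin), phased reads are
  same-strand head-to-tail runs of 2–6, the rest uniform background. Read
  lengths are drawn from a discrete 23–35 nt distribution whose default
  weights put ~73% of mass in the 26–32 nt mode; 1U/10A biases overwrite
  the corresponding read bases with the given probabilities (T stands for U
  in DNA space).
* **Expression/ChIP**: Poisson counts at expected
  rpkm × kb × library-size/10^6; ChIP counts scale the control rate by the
  programmed per-feature enrichment. Count tables (not per-read records) are
  emitted, since every consumer in the pipeline is count-based.

What passing these tests shows — and does not. The generator reproduces the
statistical structure the analysis assumes (junction geometry, signature
pair structure, copy divergence, Poisson counting noise), so the tests
demonstrate correctness of the operations and estimators under that
structure. It does not emulate realistic nanopore error profiles, PCR
duplicates, chimeric reads, reference assembly errors, or transposition
mechanism details; performance on real libraries depends additionally on
those factors.

## Determinism and problem sizes

One config seed feeds fixed per-stage substreams; rerunning the pipeline
with the same config is byte-identical (the manifest stores parameters, the
seed and output checksums, no timestamps). The bundled study runs at desk
scale by design — two 100-kb chromosomes, a 6-kb element, 12 planted copies,
a 2,000-read small-RNA library; the recovery experiments use 50 planted
inserts over 20 seeds, ~200× site coverage for allele composition, and
200-read genotyping mixtures. These sizes are where the statistical checks
(3σ binomial/Poisson bounds, empirical nulls over 20 seeds) are already
well-powered while the whole suite runs in well under a minute.

## Known limitations

* The homology aligner is ungapped; diverged families with indel-rich
  copies would need the external-tool adapter seam.
* `align_copies` assumes near-identical, broadly length-matched copies;
  heavily truncated copies should be assigned to families first and aligned
  only over their retained region.
* Manual site exclusions (e.g. a locus with irregular supporting evidence)
  are configuration, not code: no computational rule decides them.
* Ping-pong/phasing weighting uses unique species with multiplicative copy
  numbers; per-read weighting is available via the brute-force-equivalent
  placement counting but the species convention is the default and the one
  the invariance tests pin down.
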