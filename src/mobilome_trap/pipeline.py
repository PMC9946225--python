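"""End-to-end orchestration: simulate -> detect -> group -> signatures ->
snp -> genotype -> express/chip, from a single config with one seed.

Every stage reads and writes documented file formats (FASTA, VCF-BND, BED,
TSV, JSON), so any stage can be re-run in isolation on another stage's
outputs.  One config seed feeds deterministic per-stage substreams; rerunning
with the same config gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import core_io, expression, homology, inserts, signatures, snp, synthetic
from .core_io import GenomicInterval

log = logging.getLogger("mobilome_trap")

_STAGE_OFFSETS = {
    "genome": 1, "element": 2, "plant": 3, "breakends": 4, "smallrna": 5,
    "snp_reads": 6, "long_reads": 7, "expression": 8,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31."""
    return (seed * 1_000_003 + _STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the analysis defaults.

    The detection/grouping/signature defaults (max_gap 100, size bounds
    100/10000, e-value 1e-100, >= 5 members, >= 23 nt piRNAs, 23-32 nt
    ping-pong window, 100 bp genotyping flank, 33 nt tiling, RPKM > 10) are
    the thresholds the analysis is defined by; the simulation block sets the
    synthetic study conditions.
    """

    seed: int = 0
    # simulation
    n_chrom: int = 2
    chrom_length: int = 100_000
    gc_fraction: float = 0.5
    element_length: int = 6_000
    ltr_length: int = 400
    snp_rate: float = 0.003
    n_copies: int = 12
    het_fraction: float = 1.0
    jitter_sd: float = 0.0
    fp_per_mb: float = 0.0
    n_small_rna: int = 2_000
    pingpong_fraction: float = 0.5
    phasing_fraction: float = 0.25
    first_u_bias: float = 0.8
    tenth_a_bias: float = 0.6
    # analysis thresholds
    max_gap: int = 100
    min_insert_len: int = 100
    max_insert_len: int = 10_000
    evalue_max: float = 1e-100
    min_members: int = 5
    pirna_min_len: int = 23
    pingpong_window: tuple[int, int] = (23, 32)
    flank: int = 100
    tile_window: int = 33
    rpkm_threshold: float = 10.0
    log_level: str = "info"

    def __post_init__(self):
        positive = ["n_chrom", "chrom_length", "element_length", "ltr_length",
                    "n_copies", "max_gap", "min_insert_len", "max_insert_len",
                    "evalue_max", "min_members", "pirna_min_len", "flank",
                    "tile_window", "rpkm_threshold", "n_small_rna"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config parameter {name} must be positive")
        if self.log_level not in ("debug", "info", "warn"):
            raise ValueError(f"unknown log level {self.log_level!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pingpong_window" in data:
            data = dict(data)
            data["pingpong_window"] = tuple(data["pingpong_window"])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_insert_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor_chrom\tanchor_start\tanchor_end\tdonor_chrom\t"
                 "donor_start\tdonor_end\torientation\tlength\tsupport\n")
        for c in calls:
            support = ";".join(",".join(s) for s in c.support)
            fh.write(f"{c.anchor.chrom}\t{c.anchor.start}\t{c.anchor.end}\t"
                     f"{c.donor.chrom}\t{c.donor.start}\t{c.donor.end}\t"
                     f"{c.orientation}\t{c.length}\t{support}\n")


def write_groups_tsv(groups, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tn_members\tfocus\trepresentative\told_area_bp\t"
                 "new_area_bp\tactivity_ratio\tmembers\n")
        for g in groups:
            ratio = ("inf" if g.ratio_infinite
                     else "" if g.activity_ratio is None
                     else f"{g.activity_ratio:.6g}")
            fh.write(f"{g.group_id}\t{len(g.member_ids)}\t{int(g.focus)}\t"
                     f"{g.representative_id or ''}\t{g.old_area_bp or 0}\t"
                     f"{g.new_area_bp or 0}\t{ratio}\t"
                     f"{','.join(g.member_ids)}\n")


def write_signature_tsv(result, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tfrequency\n")
        if result.frequencies is not None:
            for pos, freq in zip(result.positions, result.frequencies):
                fh.write(f"{pos}\t{freq:.10g}\n")


def signature_json(result) -> dict:
    return {
        "kind": result.kind,
        "focal_position": result.focal_position,
        "background_positions": list(result.background_positions),
        "z_score": None if result.z_score is None else round(result.z_score, 6),
        "flagged": result.flagged,
    }


def run_full_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages into ``out_dir``; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    level = {"debug": logging.DEBUG, "info": logging.INFO,
             "warn": logging.WARNING}[config.log_level]
    log.setLevel(level)
    manifest: dict = {
        "parameters": {f.name: getattr(config, f.name)
                       for f in fields(config)},
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    manifest["parameters"]["pingpong_window"] = list(config.pingpong_window)

    # --- stage: simulate ------------------------------------------------
    log.info("simulate: genome + element expansion")
    genome = synthetic.simulate_genome(
        config.n_chrom, config.chrom_length, config.gc_fraction,
        seed=stage_seed(config.seed, "genome"))
    element = synthetic.random_element(
        "elementA", config.element_length, "LTR", config.ltr_length,
        config.snp_rate, seed=stage_seed(config.seed, "element"))
    haplotypes, truth = synthetic.plant_transposon_copies(
        genome, element, config.n_copies, config.het_fraction,
        seed=stage_seed(config.seed, "plant"))
    breakends = synthetic.emit_breakends_from_truth(
        truth, config.jitter_sd, config.fp_per_mb,
        seed=stage_seed(config.seed, "breakends"))
    ref_genome = truth.reference_genome
    core_io.write_fasta(ref_genome, out / "reference.fa")
    core_io.write_breakends(breakends, out / "breakends.vcf")
    core_io.write_bed([i.acceptor for i in truth.planted_inserts],
                      out / "planted_inserts.bed",
                      names=[i.copy_id for i in truth.planted_inserts])
    manifest["stages"].append("simulate")

    # --- stage: detect --------------------------------------------------
    log.info("detect: pair breakends and size-filter")
    loaded = core_io.read_breakends(out / "breakends.vcf")
    calls, residual = inserts.pair_breakends_to_inserts(loaded, config.max_gap)
    filtered = inserts.filter_inserts_by_size(
        calls, config.min_insert_len, config.max_insert_len)
    write_insert_calls_tsv(filtered.kept, out / "inserts.tsv")
    core_io.write_bed([c.anchor for c in filtered.kept], out / "anchors.bed")
    core_io.write_bed([c.donor for c in filtered.kept], out / "donors.bed")
    report = inserts.evaluate_insert_calls(filtered.kept, truth)
    manifest["detect"] = {
        "n_breakends": len(loaded), "n_calls": len(calls),
        "n_residual": len(residual),
        "n_kept": len(filtered.kept), "n_below": filtered.n_below,
        "n_above": filtered.n_above,
        "precision": round(report.precision, 6),
        "recall": round(report.recall, 6),
    }
    manifest["stages"].append("detect")

    # --- stage: group ---------------------------------------------------
    log.info("group: homology grouping + activity ratio")
    insert_seqs = {
        f"insert_{i + 1}": ref_genome[c.donor.chrom][c.donor.start:c.donor.end]
        for i, c in enumerate(filtered.kept)
    }
    groups = homology.group_inserts(insert_seqs, ref_genome,
                                    config.evalue_max, config.min_members)
    write_groups_tsv(groups, out / "groups.tsv")
    manifest["group"] = {
        "n_groups": len(groups),
        "n_focus": sum(g.focus for g in groups),
        "top_ratio": (groups[0].activity_ratio if groups and
                      groups[0].activity_ratio is not None else None),
    }
    manifest["stages"].append("group")

    # --- stage: signatures ---------------------------------------------
    log.info("signatures: ping-pong and phasing z-scores")
    locus = {"elementA": element.consensus}
    records, _sr_truth = synthetic.simulate_small_rna_library(
        locus, config.n_small_rna, config.pingpong_fraction,
        config.phasing_fraction, config.first_u_bias, config.tenth_a_bias,
        seed=stage_seed(config.seed, "smallrna"))
    pp_in = signatures.filter_pirna_alignments(records,
                                               *config.pingpong_window)
    ph_in = signatures.filter_pirna_alignments(records, config.pirna_min_len)
    pp = signatures.pingpong_zscore(pp_in)
    ph = signatures.phasing_zscore(ph_in)
    hist, frac = signatures.length_distribution(records, window=(26, 32))
    write_signature_tsv(pp, out / "pingpong.tsv")
    write_signature_tsv(ph, out / "phasing.tsv")
    region = GenomicInterval("elementA", 0, len(element.consensus))
    sense, antisense = signatures.stranded_coverage(ph_in, region)
    _write_bedgraph(sense, region, out / "coverage_sense.bedgraph")
    _write_bedgraph(-antisense, region, out / "coverage_antisense.bedgraph")
    manifest["signatures"] = {
        "pingpong": signature_json(pp),
        "phasing": signature_json(ph),
        "fraction_26_32": round(frac, 6),
    }
    manifest["stages"].append("signatures")

    # --- stage: snp -----------------------------------------------------
    log.info("snp: copy alignment, site calling, allele composition")
    copies = {"reference": element.consensus}
    for ins in truth.planted_inserts[:8]:
        copies[ins.copy_id] = ins.donor_sequence
    aln = snp.align_copies(copies, "reference")
    sites = snp.call_snp_sites(aln)
    _write_sites_tsv(sites, out / "snp_sites.tsv")
    comp_records = _simulate_snp_reads(copies, config,
                                       stage_seed(config.seed, "snp_reads"))
    table = snp.allele_composition(comp_records, element.consensus, sites)
    table.to_csv(out / "allele_composition.tsv", sep="\t")
    manifest["snp"] = {"n_sites": len(sites),
                       "n_copies": len(copies)}
    manifest["stages"].append("snp")

    # --- stage: genotype ------------------------------------------------
    log.info("genotype: with/without read support at one insertion site")
    geno = _genotype_first_insert(ref_genome, truth, config)
    with open(out / "genotype.tsv", "w") as fh:
        fh.write("site\tn_with\tn_without\tratio\n")
        site = truth.planted_inserts[0].acceptor
        ratio = "" if geno.ratio is None else f"{geno.ratio:.6g}"
        fh.write(f"{site.chrom}:{site.start}\t{geno.n_with}\t"
                 f"{geno.n_without}\t{ratio}\n")
    manifest["genotype"] = {"n_with": geno.n_with,
                            "n_without": geno.n_without,
                            "ratio": geno.ratio}
    manifest["stages"].append("genotype")

    # --- stage: express / chip -----------------------------------------
    log.info("express: RPKM, relative expression, ChIP enrichment")
    feature_lengths = {f"tp{i}": 1000 + 500 * i for i in range(1, 9)}
    day_targets = {
        "day0": {f: 40.0 if f == "tp1" else 15.0 for f in feature_lengths},
        "day10": {f: 10.0 if f == "tp1" else 20.0 for f in feature_lengths},
        "day20": {f: 4.0 if f == "tp1" else 30.0 for f in feature_lengths},
    }
    library_sizes = {lib: 1_000_000 for lib in day_targets}
    enrichment = {f: 4.0 if f == "tp1" else 1.0 for f in feature_lengths}
    sim = synthetic.simulate_expression_tracks(
        feature_lengths, day_targets, library_sizes, enrichment,
        seed=stage_seed(config.seed, "expression"))
    records_df = expression.rpkm_table(sim.counts, feature_lengths,
                                       library_sizes)
    rel = expression.relative_expression(records_df, "day0")
    rel.to_csv(out / "expression.tsv", sep="\t", index=False)
    expressed = expression.expressed_transposon_filter(
        records_df, list(day_targets), config.rpkm_threshold)
    enr = expression.chip_enrichment(sim.chip_counts.to_dict(),
                                     sim.control_counts.to_dict(),
                                     feature_lengths, 1_000_000, 1_000_000)
    enr.to_csv(out / "chip_enrichment.tsv", sep="\t", index=False)
    expression.boxplot_summary(rel).to_csv(out / "expression_boxplot.tsv",
                                           sep="\t", index=False)
    manifest["expression"] = {
        "n_expressed": len(expressed),
        "tp1_log2_enrichment": round(
            float(enr.set_index("feature_id").at["tp1", "log2_enrichment"]), 6),
    }
    manifest["stages"].append("express")

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    _write_json(manifest, out / "manifest.json")
    return manifest


def _write_bedgraph(values, region, path) -> None:
    with open(path, "w") as fh:
        run_start = 0
        prev = values[0] if len(values) else 0
        for i in range(1, len(values) + 1):
            cur = values[i] if i < len(values) else None
            if cur != prev:
                fh.write(f"{region.chrom}\t{region.start + run_start}\t"
                         f"{region.start + i}\t{prev}\n")
                run_start, prev = i, cur


def _write_sites_tsv(sites, path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_position\talleles\n")
        for s in sites:
            alleles = ",".join(f"{cid}:{nt}" for cid, nt in s.alleles)
            fh.write(f"{s.ref_position}\t{alleles}\n")


def _simulate_snp_reads(copies, config, seed):
    """Ungapped 33-nt tiles from two copies at 50/50, as piRNA-like records."""
    from .core_io import AlignmentRecord
    rng = np.random.default_rng(seed)
    ids = [cid for cid in copies if cid != "reference"][:2] or ["reference"]
    records = []
    n = 400
    for i in range(n):
        cid = ids[rng.integers(len(ids))]
        seq = copies[cid]
        w = config.tile_window
        start = int(rng.integers(0, len(seq) - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        s = seq[start:start + w]
        if strand == "-":
            s = core_io.revcomp(s)
        records.append(AlignmentRecord(
            read_id=f"snpread_{i}",
            interval=GenomicInterval("reference", start, start + w, strand),
            read_length=w, sequence=s))
    return {"piRNA": records}


def _genotype_first_insert(ref_genome, truth, config):
    ins = truth.planted_inserts[0]
    chrom, p = ins.acceptor.chrom, ins.acceptor.start
    flank_seq = 2000
    left = ref_genome[chrom][max(0, p - flank_seq):p]
    right = ref_genome[chrom][p:p + flank_seq]
    allele_without = left + right
    allele_with = left + ins.donor_sequence + right
    n_with_reads, n_without_reads = 14, 6
    rng_seed = stage_seed(config.seed, "long_reads")
    reads = {}
    reads_w, _ = synthetic.simulate_long_reads(
        {"with": {"site": allele_with}}, mean_len=3000, len_sd=300,
        error_rate=0.02,
        depth=n_with_reads * 3000 / len(allele_with), seed=rng_seed)
    reads_o, _ = synthetic.simulate_long_reads(
        {"without": {"site": allele_without}}, mean_len=3000, len_sd=300,
        error_rate=0.02,
        depth=n_without_reads * 3000 / len(allele_without), seed=rng_seed + 1)
    reads.update({f"w_{k}": v for k, v in reads_w.items()})
    reads.update({f"o_{k}": v for k, v in reads_o.items()})
    return inserts.genotype_insertion_site(
        reads, allele_with, allele_without, len(left), config.flank,
        site=ins.acceptor)
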