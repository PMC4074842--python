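"""Orchestration: simulate -> detect -> evaluate, plus writers and reports.

``run_pipeline`` drives the four detectors over one matched tumor/normal
input — either a self-contained simulation (embedded
:class:`~somaticscan.simdata.SimulationConfig`) or a pair of SAM files plus
a reference FASTA — and writes the standard-format outputs:

* somatic SNVs and indels as VCF v4.2 (per-strand depths and alt counts in
  FORMAT, KS distances / profile provenance / filter status in INFO),
* per-window copy-number log2 ratios as BedGraph, masked windows and
  gain/loss segments as BED,
* translocations as BEDPE with support, z-score and somatic flag, plus a
  per-window proportion TSV for diagnostics,
* in simulation mode, the truth set and a precision/recall report
  (TSV + JSON) per event class.

The evaluation matching rules: SNVs match on (chrom, pos, alt); indels on
(chrom, type) with start within +/-5 bp; CNV segments need reciprocal
overlap >= 0.5 and the same direction; translocations need both breakpoint
regions within 2 kb of the true breakpoints.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cnvscan, indelsom, simdata, snvcall, txscan
from .records import read_table_from_sam

logger = logging.getLogger("somaticscan")

__all__ = [
    "PipelineConfig", "ClassMetrics", "EvaluationReport", "ResultBundle",
    "run_pipeline", "evaluate_against_truth", "summarize_damaging_fraction",
    "configure_logging",
]

STAGES = ("snv", "cnv", "indel", "tx")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    output_dir: str
    reference: str | None = None  # FASTA path (non-simulated runs)
    normal: str | None = None  # SAM path
    tumor: str | None = None  # SAM path
    snv_params: snvcall.SnvParams = field(default_factory=snvcall.SnvParams.lenient)
    snv_profile: str = "lenient"  # "strict" | "lenient" | "both" | "custom"
    cnv_params: cnvscan.CnvParams = field(default_factory=cnvscan.CnvParams)
    indel_params: indelsom.IndelParams = field(default_factory=indelsom.IndelParams)
    tx_params: txscan.TxParams = field(default_factory=txscan.TxParams)
    simulation: simdata.SimulationConfig | None = None
    write_alignments: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("reference", "normal", "tumor"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} path required for non-simulated runs")
                if not os.path.exists(path):
                    raise ValueError(f"{name} path does not exist: {path}")
        else:
            self.simulation.validate()
        if self.snv_profile not in ("strict", "lenient", "both", "custom"):
            raise ValueError(f"unknown SNV profile {self.snv_profile!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, block):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - fields
            if unknown:
                raise ValueError(f"unknown keys for {klass.__name__}: {sorted(unknown)}")
            return klass(**block)

        kwargs: dict = {"output_dir": raw["output_dir"]}
        for key in ("reference", "normal", "tumor", "snv_profile",
                    "write_alignments", "log_level", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "snv_params" in raw:
            kwargs["snv_params"] = build(snvcall.SnvParams, raw["snv_params"])
        if "cnv_params" in raw:
            kwargs["cnv_params"] = build(cnvscan.CnvParams, raw["cnv_params"])
        if "indel_params" in raw:
            kwargs["indel_params"] = build(indelsom.IndelParams, raw["indel_params"])
        if "tx_params" in raw:
            kwargs["tx_params"] = build(txscan.TxParams, raw["tx_params"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            sim["chromosomes"] = [tuple(c) for c in sim["chromosomes"]]
            for key, klass in (("snvs", simdata.SnvSpike),
                               ("indels", simdata.IndelSpike),
                               ("cnvs", simdata.CnvSpike),
                               ("translocations", simdata.TxSpike),
                               ("hotspots", simdata.HotspotSpike)):
                if key in sim:
                    sim[key] = [build(klass, b) for b in sim[key]]
            kwargs["simulation"] = build(simdata.SimulationConfig, sim)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)


# ---------------------------------------------------------------------------
# writers (plain-text standard formats)
# ---------------------------------------------------------------------------

_VCF_HEADER = "##fileformat=VCFv4.2\n"


def write_snv_vcf(calls: Sequence[snvcall.SomaticSnv], path: str,
                  contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write('##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">\n')
        fh.write('##INFO=<ID=PROFILE,Number=1,Type=String,Description="Threshold profile provenance">\n')
        fh.write('##INFO=<ID=NKS,Number=1,Type=Float,Description="Normal combined KS distance">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Trimmed depth">\n')
        fh.write('##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Alt reads forward strand">\n')
        fh.write('##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Alt reads reverse strand">\n')
        fh.write('##FORMAT=<ID=DPF,Number=1,Type=Integer,Description="Depth forward strand">\n')
        fh.write('##FORMAT=<ID=DPR,Number=1,Type=Integer,Description="Depth reverse strand">\n')
        for c, l in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
        for rec in sorted(calls, key=lambda r: (r.chrom, r.pos)):
            info = (f"SOMATIC;PROFILE={rec.profile};"
                    f"NKS={rec.normal_call.combined_distance:.4f}")
            fmt = "DP:ADF:ADR:DPF:DPR"
            sample = (f"{rec.tumor_depth_fwd + rec.tumor_depth_rev}:"
                      f"{rec.tumor_alt_fwd}:{rec.tumor_alt_rev}:"
                      f"{rec.tumor_depth_fwd}:{rec.tumor_depth_rev}")
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                     f"{info}\t{fmt}\t{sample}\n")


def write_indel_vcf(candidates: Sequence[indelsom.IndelCandidate], path: str,
                    contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="somatic, germline_or_artifact or low_normal_coverage">\n')
        fh.write('##INFO=<ID=EVENT,Number=1,Type=String,Description="ins or del">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Indel length">\n')
        fh.write('##FORMAT=<ID=TS,Number=1,Type=Integer,Description="Tumor supporting reads">\n')
        fh.write('##FORMAT=<ID=ND,Number=1,Type=Integer,Description="Normal overlapping depth">\n')
        fh.write('##FORMAT=<ID=NI,Number=1,Type=Integer,Description="Normal indel-bearing reads">\n')
        for c, l in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FILTER=<ID=germline_or_artifact,Description="Indel evidence in matched normal region">\n')
        fh.write('##FILTER=<ID=low_normal_coverage,Description="Insufficient normal depth in region">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
        for c in sorted(candidates, key=lambda c: (c.chrom, c.start)):
            filt = "PASS" if c.status == "somatic" else c.status
            length = len(c.sequence) if c.sequence else (c.end - c.start)
            alt = "<DEL>" if c.kind == "del" else "<INS>"
            info = f"STATUS={c.status};EVENT={c.kind};SVLEN={length}"
            fh.write(f"{c.chrom}\t{c.start + 1}\t.\tN\t{alt}\t.\t{filt}\t{info}\t"
                     f"TS:ND:NI\t{c.tumor_support}:{c.normal_depth}:{c.normal_indel_reads}\n")


def write_bedgraph(windows: Sequence[cnvscan.CoverageWindow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="tumor_normal_log2"\n')
        for w in windows:
            if not w.masked and w.log2_ratio is not None:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.log2_ratio:.4f}\n")


def write_masked_bed(windows: Sequence[cnvscan.CoverageWindow], path: str) -> None:
    with open(path, "w") as fh:
        for w in windows:
            if w.masked:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\thigh_repeat\n")


def write_segments_bed(segments: Sequence[cnvscan.CnvSegment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t"
                     f"{s.mean_log2:.4f}\t.\n")


def write_tx_bedpe(calls: Sequence[txscan.TranslocationCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom_a}\t{c.start_a}\t{c.end_a}\t"
                     f"{c.chrom_b}\t{c.start_b}\t{c.end_b}\t"
                     f"tx\t{c.support}\t+\t+\t"
                     f"z={c.z_score:.3f};somatic={'1' if c.somatic else '0'}\n")


def write_tx_windows_tsv(windows: Sequence[txscan.DiscordantWindow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttotal\tdiscordant\thighest_hit\thit_count\tproportion\n")
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.total_reads}\t"
                     f"{w.discordant_reads}\t{w.highest_hit or '.'}\t"
                     f"{w.hit_count}\t{w.proportion:.6f}\n")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None


@dataclass
class EvaluationReport:
    classes: dict[str, ClassMetrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {name: {"tp": m.tp, "fp": m.fp, "fn": m.fn,
                       "precision": m.precision, "recall": m.recall}
                for name, m in self.classes.items()}

    def write(self, tsv_path: str, json_path: str) -> None:
        with open(tsv_path, "w") as fh:
            fh.write("class\ttp\tfp\tfn\tprecision\trecall\n")
            for name, m in self.classes.items():
                prec = "NA" if m.precision is None else f"{m.precision:.4f}"
                rec = "NA" if m.recall is None else f"{m.recall:.4f}"
                fh.write(f"{name}\t{m.tp}\t{m.fp}\t{m.fn}\t{prec}\t{rec}\n")
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _match_greedy(calls: list, truths: list, matches) -> ClassMetrics:
    """Greedy one-to-one matching; each truth is credited at most once."""
    m = ClassMetrics()
    used = [False] * len(truths)
    for call in calls:
        hit = None
        for i, t in enumerate(truths):
            if not used[i] and matches(call, t):
                hit = i
                break
        if hit is None:
            m.fp += 1
        else:
            used[hit] = True
            m.tp += 1
    m.fn = used.count(False)
    return m


def _tx_region_near(region: tuple[str, int, int], chrom: str, pos: int,
                    tol: int = 2000) -> bool:
    if region[0] != chrom:
        return False
    if region[1] <= pos < region[2]:
        return True
    return min(abs(pos - region[1]), abs(pos - (region[2] - 1))) <= tol


def evaluate_against_truth(
    truth: simdata.TruthSet,
    snv_calls: Sequence[snvcall.SomaticSnv] = (),
    indel_calls: Sequence[indelsom.IndelCandidate] = (),
    cnv_segments: Sequence[cnvscan.CnvSegment] = (),
    tx_calls: Sequence[txscan.TranslocationCall] = (),
    indel_tolerance: int = 5,
) -> EvaluationReport:
    """Precision/recall of each detector's somatic output against the truth."""
    report = EvaluationReport()

    true_snvs = [t for t in truth.snvs if t.origin == "somatic"]
    report.classes["snv"] = _match_greedy(
        list(snv_calls), true_snvs,
        lambda c, t: c.chrom == t.chrom and c.pos == t.pos + 1 and c.alt == t.alt)

    true_indels = [t for t in truth.indels if t.origin == "somatic"]
    somatic_indels = [c for c in indel_calls if c.status == "somatic"]
    report.classes["indel"] = _match_greedy(
        somatic_indels, true_indels,
        lambda c, t: (c.chrom == t.chrom and c.kind == t.kind
                      and abs(c.start - t.start) <= indel_tolerance))

    true_cnvs = [t for t in truth.cnv_segments if t.copy_ratio != 1.0]

    def cnv_match(seg: cnvscan.CnvSegment, t: simdata.TruthCnv) -> bool:
        if seg.chrom != t.chrom:
            return False
        want = "gain" if t.copy_ratio > 1.0 else "loss"
        if seg.direction != want:
            return False
        inter = min(seg.end, t.end) - max(seg.start, t.start)
        if inter <= 0:
            return False
        return (inter / (seg.end - seg.start) >= 0.5
                and inter / (t.end - t.start) >= 0.5)

    report.classes["cnv"] = _match_greedy(list(cnv_segments), true_cnvs, cnv_match)

    true_tx = [t for t in truth.translocations if t.origin == "somatic"]

    def tx_match(c: txscan.TranslocationCall, t: simdata.TruthTx) -> bool:
        fwd = (_tx_region_near(c.region_a(), t.chrom_a, t.pos_a)
               and _tx_region_near(c.region_b(), t.chrom_b, t.pos_b))
        rev = (_tx_region_near(c.region_a(), t.chrom_b, t.pos_b)
               and _tx_region_near(c.region_b(), t.chrom_a, t.pos_a))
        return fwd or rev

    report.classes["tx"] = _match_greedy(list(tx_calls), true_tx, tx_match)
    return report


def summarize_damaging_fraction(total_coding: int, damaging: int) -> int:
    """Percentage of coding variants predicted damaging, to the nearest
    integer (half away from zero)."""
    if total_coding <= 0:
        raise ValueError("total_coding must be positive")
    if not (0 <= damaging <= total_coding):
        raise ValueError("damaging must be between 0 and total_coding")
    return int(math.floor(100.0 * damaging / total_coding + 0.5))


# ---------------------------------------------------------------------------
# SNV stage helpers
# ---------------------------------------------------------------------------

def _loosest_snv_params(config: PipelineConfig) -> snvcall.SnvParams:
    if config.snv_profile == "strict":
        return snvcall.SnvParams.strict()
    if config.snv_profile == "custom":
        return config.snv_params
    return snvcall.SnvParams.lenient()


def _snv_stage_simulated(
    reference: dict[str, np.ndarray],
    normal: simdata.SimulatedSample,
    tumor: simdata.SimulatedSample,
    config: PipelineConfig,
) -> list[snvcall.SomaticSnv]:
    screen = _loosest_snv_params(config)
    loci: list[tuple[str, int]] = []
    for chrom in tumor.chrom_names:
        counts, _ = simdata.base_count_arrays(tumor, chrom)
        mask = snvcall.consensus_candidate_mask(reference[chrom], counts, screen)
        loci.extend((chrom, int(p)) for p in np.flatnonzero(mask))
    logger.info("SNV stage: %d candidate loci after consensus pre-screen", len(loci))
    normal_cols = simdata.pileup_columns(normal, reference, loci)
    tumor_cols = simdata.pileup_columns(tumor, reference, loci)
    return snvcall.call_somatic_snvs(normal_cols, tumor_cols,
                                     params=config.snv_params,
                                     profile=config.snv_profile)


def _pileup_columns_from_sam(sam_path: str, fasta_path: str) -> list[snvcall.PileupColumn]:
    import pysam

    cols = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as bam, \
            pysam.FastaFile(fasta_path) as fasta:
        for column in bam.pileup(min_base_quality=0, truncate=False):
            chrom = column.reference_name
            pos = column.reference_pos
            ref = fasta.fetch(chrom, pos, pos + 1).upper()
            if ref not in snvcall.BASE_ORDER:
                continue
            fwd: list[tuple[str, int]] = []
            rev: list[tuple[str, int]] = []
            for p in column.pileups:
                if p.is_del or p.is_refskip or p.query_position is None:
                    continue
                aln = p.alignment
                base = aln.query_sequence[p.query_position].upper()
                if base not in snvcall.BASE_ORDER:
                    continue
                q = aln.query_qualities[p.query_position]
                (rev if aln.is_reverse else fwd).append((base, int(q)))
            if fwd or rev:
                cols.append(snvcall.PileupColumn(chrom, pos + 1, ref, fwd, rev))
    return cols


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

@dataclass
class ResultBundle:
    output_dir: str
    paths: dict[str, str]
    snv_calls: list = field(default_factory=list)
    indel_candidates: list = field(default_factory=list)
    cnv_windows: list = field(default_factory=list)
    cnv_segments: list = field(default_factory=list)
    tx_calls: list = field(default_factory=list)
    tx_windows: list = field(default_factory=list)
    report: EvaluationReport | None = None
    truth: simdata.TruthSet | None = None


def run_pipeline(config: PipelineConfig, only: Sequence[str] | None = None) -> ResultBundle:
    """Run the requested detector stages and write all outputs.

    ``only`` restricts to a subset of ("snv", "cnv", "indel", "tx");
    evaluation against the truth set runs in simulation mode whenever the
    corresponding stage ran.
    """
    config.validate()
    stages = tuple(only) if only else STAGES
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    os.makedirs(config.output_dir, exist_ok=True)
    paths: dict[str, str] = {}
    bundle = ResultBundle(config.output_dir, paths)

    if config.simulation is not None:
        sim = config.simulation
        logger.info("simulating reference and samples (seed=%d)", sim.seed)
        reference = simdata.simulate_reference(sim)
        normal_sample, tumor_sample, truth = simdata.simulate_pair(sim, reference)
        bundle.truth = truth
        normal_table = normal_sample.to_read_table()
        tumor_table = tumor_sample.to_read_table()
        chrom_lengths = sim.chrom_lengths()
        truth_paths = simdata.write_truth(truth, config.output_dir, reference)
        paths.update({f"truth_{k}": v for k, v in truth_paths.items()})
        if config.write_alignments:
            paths["normal_sam"] = os.path.join(config.output_dir, "normal.sam")
            paths["tumor_sam"] = os.path.join(config.output_dir, "tumor.sam")
            simdata.emit_alignments(normal_sample, paths["normal_sam"])
            simdata.emit_alignments(tumor_sample, paths["tumor_sam"])
    else:
        import pysam

        logger.info("loading alignments from SAM")
        normal_table = read_table_from_sam(config.normal)
        tumor_table = read_table_from_sam(config.tumor)
        chrom_lengths = dict(tumor_table.chrom_lengths)
        truth = None
        with pysam.FastaFile(config.reference) as fa:
            reference = {c: simdata.encode_seq(fa.fetch(c)) for c in fa.references}

    if "snv" in stages:
        logger.info("stage snv")
        if config.simulation is not None:
            bundle.snv_calls = _snv_stage_simulated(reference, normal_sample,
                                                    tumor_sample, config)
        else:
            normal_cols = _pileup_columns_from_sam(config.normal, config.reference)
            tumor_cols = _pileup_columns_from_sam(config.tumor, config.reference)
            bundle.snv_calls = snvcall.call_somatic_snvs(
                normal_cols, tumor_cols, params=config.snv_params,
                profile=config.snv_profile)
        paths["snv_vcf"] = os.path.join(config.output_dir, "somatic_snvs.vcf")
        write_snv_vcf(bundle.snv_calls, paths["snv_vcf"], chrom_lengths)
        logger.info("stage snv: %d somatic SNVs", len(bundle.snv_calls))

    if "cnv" in stages:
        logger.info("stage cnv")
        windows, segments = cnvscan.scan_cnv(normal_table, tumor_table,
                                             chrom_lengths, config.cnv_params)
        bundle.cnv_windows, bundle.cnv_segments = windows, segments
        paths["cnv_bedgraph"] = os.path.join(config.output_dir, "cnv_log2.bedgraph")
        paths["cnv_masked_bed"] = os.path.join(config.output_dir, "cnv_masked.bed")
        paths["cnv_segments_bed"] = os.path.join(config.output_dir, "cnv_segments.bed")
        write_bedgraph(windows, paths["cnv_bedgraph"])
        write_masked_bed(windows, paths["cnv_masked_bed"])
        write_segments_bed(segments, paths["cnv_segments_bed"])
        logger.info("stage cnv: %d windows, %d segments", len(windows), len(segments))

    if "indel" in stages:
        logger.info("stage indel")
        bundle.indel_candidates = indelsom.call_somatic_indels(
            tumor_table, normal_table, config.indel_params)
        paths["indel_vcf"] = os.path.join(config.output_dir, "somatic_indels.vcf")
        write_indel_vcf(bundle.indel_candidates, paths["indel_vcf"], chrom_lengths)
        n_som = sum(1 for c in bundle.indel_candidates if c.status == "somatic")
        logger.info("stage indel: %d candidates, %d somatic",
                    len(bundle.indel_candidates), n_som)

    if "tx" in stages:
        logger.info("stage tx")
        calls, windows = txscan.scan_translocations(tumor_table, normal_table,
                                                    config.tx_params)
        bundle.tx_calls, bundle.tx_windows = calls, windows
        paths["tx_bedpe"] = os.path.join(config.output_dir, "translocations.bedpe")
        paths["tx_windows_tsv"] = os.path.join(config.output_dir, "tx_windows.tsv")
        write_tx_bedpe(calls, paths["tx_bedpe"])
        write_tx_windows_tsv(windows, paths["tx_windows_tsv"])
        logger.info("stage tx: %d somatic calls", len(calls))

    if config.simulation is not None:
        bundle.report = evaluate_against_truth(
            truth,
            snv_calls=bundle.snv_calls,
            indel_calls=bundle.indel_candidates,
            cnv_segments=bundle.cnv_segments,
            tx_calls=bundle.tx_calls,
            indel_tolerance=config.indel_params.flank)
        bundle.report.classes = {k: v for k, v in bundle.report.classes.items()
                                 if k in stages}
        paths["report_tsv"] = os.path.join(config.output_dir, "evaluation.tsv")
        paths["report_json"] = os.path.join(config.output_dir, "evaluation.json")
        bundle.report.write(paths["report_tsv"], paths["report_json"])

    return bundle
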