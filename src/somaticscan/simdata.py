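"""Matched tumor/normal paired-end read simulator with a known truth set.

The detectors in this package assume a particular statistical structure in
their input: diploid germline genotypes shared by both samples, somatic
alleles diluted by tumor cellularity, an approximately normal insert-size
distribution, locally uniform fragment placement modulated by copy number,
and clustered interchromosomal discordant pairs at rearrangement junctions.
This module generates alignment data with exactly that structure, together
with the list of spiked events (:class:`TruthSet`) so that every detector can
be scored against a known answer.

The model, briefly:

* fragments are placed uniformly per chromosome at the configured mean
  sequence depth; outer insert sizes are drawn from a normal distribution
  truncated at twice the read length;
* each fragment yields a forward read at its left end and a reverse read at
  its right end (FR orientation, non-overlapping mates by construction);
* germline variants are carried by both samples at their genotype allele
  fraction (0.5 het / 1.0 hom); somatic variants appear only in the tumor at
  an observed fraction of ``VAF x cellularity`` (copy-neutral loci);
* copy-number segments multiply tumor fragment density by the configured
  ratio (ratio 0 removes every tumor fragment whose insert span overlaps the
  segment); coverage hotspots multiply density in *both* samples and stand in
  for high-repeat regions such as centromeres;
* translocations emit clustered discordant pairs whose mates map within
  ~600 bp of the two breakpoints; a small background rate of randomly placed
  chimeric pairs emulates library chimeras;
* base qualities are drawn per base from a clipped normal phred model, a
  configurable fraction of bases is assigned quality zero (with randomised
  base identity), and miscalls are injected at the per-base rate
  ``10^(-Q/10)`` implied by each emitted quality.

A single integer seed drives every stage through named substreams, so
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import truncnorm

from .records import IndelOp, ReadTable
from .snvcall import PileupColumn

__all__ = [
    "SnvSpike", "IndelSpike", "CnvSpike", "TxSpike", "HotspotSpike",
    "SimulationConfig", "TruthSnv", "TruthIndel", "TruthCnv", "TruthTx",
    "TruthSet", "SimulatedSample",
    "simulate_reference", "simulate_pair",
    "emit_alignments", "emit_pileups", "write_truth", "write_fasta",
    "base_count_arrays", "pileup_columns", "random_sites",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
# per-quality miscall probability; quality 0 bases are pure noise
_ERR_LUT = np.concatenate([[1.0], 10.0 ** (-np.arange(1, 64) / 10.0)])


def encode_seq(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.uint8)


_encode = encode_seq


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _rng(seed: int, *labels) -> np.random.Generator:
    key = zlib.crc32("/".join(map(str, labels)).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SnvSpike:
    chrom: str
    pos: int  # 0-based
    alt: str
    vaf: float = 0.5
    origin: str = "somatic"  # "somatic" | "germline"
    zygosity: str = "het"  # germline only: "het" | "hom"


@dataclass
class IndelSpike:
    chrom: str
    start: int  # 0-based first deleted base / insertion point
    kind: str  # "ins" | "del"
    length: int
    sequence: str = ""  # inserted bases; filled from reference for deletions
    vaf: float = 0.5
    origin: str = "somatic"
    zygosity: str = "het"


@dataclass
class CnvSpike:
    chrom: str
    start: int
    end: int
    copy_ratio: float  # effective tumor fragment-density ratio; 0 = homozygous deletion


@dataclass
class TxSpike:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    origin: str = "somatic"
    n_pairs: int | None = None  # default: 0.5 x sample depth


@dataclass
class HotspotSpike:
    """Coverage hotspot applied to both samples (high-repeat stand-in)."""

    chrom: str
    start: int
    end: int
    multiplier: float


@dataclass
class SimulationConfig:
    chromosomes: list[tuple[str, int]]
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    normal_depth: float = 40.0
    tumor_depth: float = 40.0
    cellularity: float = 1.0
    base_quality_mean: float = 33.0
    base_quality_sd: float = 3.0
    zero_quality_fraction: float = 0.01
    background_discordant_rate: float = 0.001
    seed: int = 0
    snvs: list[SnvSpike] = field(default_factory=list)
    indels: list[IndelSpike] = field(default_factory=list)
    cnvs: list[CnvSpike] = field(default_factory=list)
    translocations: list[TxSpike] = field(default_factory=list)
    hotspots: list[HotspotSpike] = field(default_factory=list)

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lengths = self.chrom_lengths()
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if length <= 2 * self.read_length:
                raise ValueError(f"chromosome {name!r} shorter than one fragment")
        if not (0.0 < self.cellularity <= 1.0):
            raise ValueError("cellularity must be in (0, 1]")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not (0.0 <= self.zero_quality_fraction < 1.0):
            raise ValueError("zero_quality_fraction must be in [0, 1)")
        for s in self.snvs:
            if s.chrom not in lengths or not (0 <= s.pos < lengths[s.chrom]):
                raise ValueError(f"SNV spike outside reference: {s}")
            if s.alt not in BASES:
                raise ValueError(f"SNV alt must be one of {BASES}: {s}")
        for ind in self.indels:
            if ind.chrom not in lengths:
                raise ValueError(f"indel spike on unknown chromosome: {ind}")
            hi = ind.start + (ind.length if ind.kind == "del" else 0)
            if not (0 < ind.start and hi < lengths[ind.chrom] - 1):
                raise ValueError(f"indel spike outside reference: {ind}")
            if ind.kind == "ins" and len(ind.sequence) != ind.length:
                raise ValueError(f"insertion sequence length mismatch: {ind}")
        for c in self.cnvs:
            if c.chrom not in lengths or not (0 <= c.start < c.end <= lengths[c.chrom]):
                raise ValueError(f"CNV spike outside reference: {c}")
            if c.copy_ratio < 0:
                raise ValueError("copy_ratio must be >= 0")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c in self.cnvs:
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
        for ivals in by_chrom.values():
            ivals.sort()
            for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ValueError("CNV spikes overlap on one chromosome")
        for t in self.translocations:
            for chrom, pos in ((t.chrom_a, t.pos_a), (t.chrom_b, t.pos_b)):
                if chrom not in lengths or not (0 <= pos < lengths[chrom]):
                    raise ValueError(f"translocation spike outside reference: {t}")
            if t.chrom_a == t.chrom_b:
                raise ValueError("translocation spikes must be interchromosomal")
        for h in self.hotspots:
            if h.chrom not in lengths or not (0 <= h.start < h.end <= lengths[h.chrom]):
                raise ValueError(f"hotspot outside reference: {h}")


@dataclass
class TruthSnv:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    vaf: float
    origin: str


@dataclass
class TruthIndel:
    chrom: str
    start: int
    end: int  # half-open reference footprint; end == start for insertions
    kind: str
    sequence: str
    vaf: float
    origin: str


@dataclass
class TruthCnv:
    chrom: str
    start: int
    end: int
    copy_ratio: float


@dataclass
class TruthTx:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    origin: str


@dataclass
class TruthSet:
    snvs: list[TruthSnv] = field(default_factory=list)
    indels: list[TruthIndel] = field(default_factory=list)
    cnv_segments: list[TruthCnv] = field(default_factory=list)
    translocations: list[TruthTx] = field(default_factory=list)

    def validate(self) -> None:
        loci = [(s.chrom, s.pos) for s in self.snvs]
        if len(loci) != len(set(loci)):
            raise ValueError("two truth SNVs share a locus")
        for rec in (*self.snvs, *self.indels, *self.translocations):
            if rec.origin not in ("germline", "somatic"):
                raise ValueError(f"origin not set on {rec}")


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Random reference sequences (base codes 0..3) per declared chromosome."""
    config.validate()
    ref = {}
    for name, length in config.chromosomes:
        rng = _rng(config.seed, "reference", name)
        ref[name] = rng.integers(0, 4, size=length, dtype=np.uint8)
    return ref


def write_fasta(reference: dict[str, np.ndarray], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, codes in reference.items():
            fh.write(f">{name}\n")
            seq = decode_seq(codes)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# sample container
# ---------------------------------------------------------------------------

@dataclass
class ChromReads:
    """All simulated reads on one chromosome, coordinate sorted."""

    chrom: str
    start: np.ndarray
    is_reverse: np.ndarray
    bases: np.ndarray  # (n, read_length) uint8 codes
    quals: np.ndarray  # (n, read_length) uint8 phred
    tlen: np.ndarray
    end: np.ndarray
    mate_chrom_id: np.ndarray
    mate_pos: np.ndarray
    proper: np.ndarray
    frag_id: np.ndarray
    is_read1: np.ndarray
    has_indel: np.ndarray
    indel_ops: dict[int, tuple[IndelOp, ...]]

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class SimulatedSample:
    name: str
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    read_length: int
    chroms: dict[str, ChromReads]

    def n_reads(self) -> int:
        return sum(len(c) for c in self.chroms.values())

    def to_read_table(self) -> ReadTable:
        cid = {c: i for i, c in enumerate(self.chrom_names)}
        parts = [self.chroms[c] for c in self.chrom_names if c in self.chroms]
        n = sum(len(p) for p in parts)
        chrom_ids = np.empty(n, np.int32)
        start = np.empty(n, np.int64)
        end = np.empty(n, np.int64)
        insert = np.empty(n, np.int64)
        rev = np.empty(n, bool)
        mate = np.empty(n, np.int32)
        mpos = np.empty(n, np.int64)
        proper = np.empty(n, bool)
        ops: dict[int, tuple[IndelOp, ...]] = {}
        off = 0
        for p in parts:
            k = len(p)
            sl = slice(off, off + k)
            chrom_ids[sl] = cid[p.chrom]
            start[sl] = p.start
            end[sl] = p.end
            insert[sl] = p.tlen
            rev[sl] = p.is_reverse
            mate[sl] = p.mate_chrom_id
            mpos[sl] = p.mate_pos
            proper[sl] = p.proper
            for row, o in p.indel_ops.items():
                ops[off + row] = o
            off += k
        return ReadTable(self.chrom_names, chrom_ids, start, end, insert, rev,
                         mate, mpos, proper, ops, dict(self.chrom_lengths))


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates read placements for one chromosome before materialisation."""

    def __init__(self) -> None:
        self.start: list[np.ndarray] = []
        self.is_reverse: list[np.ndarray] = []
        self.tlen: list[np.ndarray] = []
        self.mate_chrom_id: list[np.ndarray] = []
        self.mate_pos: list[np.ndarray] = []
        self.proper: list[np.ndarray] = []
        self.frag_id: list[np.ndarray] = []
        self.is_read1: list[np.ndarray] = []

    def add(self, start, is_reverse, tlen, mate_chrom_id, mate_pos, proper,
            frag_id, is_read1) -> None:
        n = len(start)
        self.start.append(np.asarray(start, np.int64))
        self.is_reverse.append(np.broadcast_to(np.asarray(is_reverse, bool), (n,)).copy())
        self.tlen.append(np.broadcast_to(np.asarray(tlen, np.int64), (n,)).copy())
        self.mate_chrom_id.append(np.broadcast_to(np.asarray(mate_chrom_id, np.int32), (n,)).copy())
        self.mate_pos.append(np.asarray(mate_pos, np.int64))
        self.proper.append(np.broadcast_to(np.asarray(proper, bool), (n,)).copy())
        self.frag_id.append(np.asarray(frag_id, np.int64))
        self.is_read1.append(np.broadcast_to(np.asarray(is_read1, bool), (n,)).copy())

    def concat(self) -> dict[str, np.ndarray]:
        if not self.start:
            return {k: np.empty(0, dtype=d) for k, d in
                    (("start", np.int64), ("is_reverse", bool), ("tlen", np.int64),
                     ("mate_chrom_id", np.int32), ("mate_pos", np.int64),
                     ("proper", bool), ("frag_id", np.int64), ("is_read1", bool))}
        return {
            "start": np.concatenate(self.start),
            "is_reverse": np.concatenate(self.is_reverse),
            "tlen": np.concatenate(self.tlen),
            "mate_chrom_id": np.concatenate(self.mate_chrom_id),
            "mate_pos": np.concatenate(self.mate_pos),
            "proper": np.concatenate(self.proper),
            "frag_id": np.concatenate(self.frag_id),
            "is_read1": np.concatenate(self.is_read1),
        }


def _draw_inserts(rng: np.random.Generator, n: int, mean: float, sd: float,
                  lo: int, hi: int) -> np.ndarray:
    if n == 0:
        return np.empty(0, np.int64)
    if sd == 0:
        return np.full(n, int(np.clip(round(mean), lo, hi)), np.int64)
    a = (lo - mean) / sd
    draws = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.round(draws).astype(np.int64), lo, hi)


def _build_truth(config: SimulationConfig, reference: dict[str, np.ndarray]) -> TruthSet:
    truth = TruthSet()
    for s in config.snvs:
        ref_base = BASES[reference[s.chrom][s.pos]]
        if ref_base == s.alt:
            raise ValueError(f"SNV spike alt equals reference base at {s.chrom}:{s.pos}")
        vaf = 1.0 if (s.origin == "germline" and s.zygosity == "hom") else (
            s.vaf if s.origin == "somatic" else 0.5)
        truth.snvs.append(TruthSnv(s.chrom, s.pos, ref_base, s.alt, vaf, s.origin))
    for ind in config.indels:
        if ind.kind == "del":
            seq = decode_seq(reference[ind.chrom][ind.start:ind.start + ind.length])
            end = ind.start + ind.length
        else:
            seq = ind.sequence.upper()
            end = ind.start
        vaf = 1.0 if (ind.origin == "germline" and ind.zygosity == "hom") else (
            ind.vaf if ind.origin == "somatic" else 0.5)
        truth.indels.append(TruthIndel(ind.chrom, ind.start, end, ind.kind, seq,
                                       vaf, ind.origin))
    for c in config.cnvs:
        truth.cnv_segments.append(TruthCnv(c.chrom, c.start, c.end, c.copy_ratio))
    for t in config.translocations:
        truth.translocations.append(TruthTx(t.chrom_a, t.pos_a, t.chrom_b, t.pos_b,
                                            t.origin))
    truth.validate()
    return truth


def simulate_pair(
    config: SimulationConfig, reference: dict[str, np.ndarray]
) -> tuple[SimulatedSample, SimulatedSample, TruthSet]:
    """Simulate the matched normal and tumor samples plus their truth set."""
    config.validate()
    lengths = config.chrom_lengths()
    for name, length in config.chromosomes:
        if name not in reference or len(reference[name]) != length:
            raise ValueError(f"reference does not match config chromosome {name!r}")
    truth = _build_truth(config, reference)
    normal = _simulate_sample(config, reference, "normal")
    tumor = _simulate_sample(config, reference, "tumor")
    return normal, tumor, truth


def _fragment_placements(config: SimulationConfig, which: str, chrom: str,
                         length: int) -> tuple[np.ndarray, np.ndarray]:
    """Fragment (start, insert) arrays for one chromosome of one sample."""
    depth = config.normal_depth if which == "normal" else config.tumor_depth
    rl = config.read_length
    n_frag = int(round(depth * length / (2.0 * rl)))
    rng = _rng(config.seed, which, "frags", chrom)
    inserts = _draw_inserts(rng, n_frag, config.insert_mean, config.insert_sd,
                            2 * rl, length - 1)
    starts = np.floor(rng.random(n_frag) * (length - inserts + 1)).astype(np.int64)

    weight = np.ones(n_frag)
    mid = starts + inserts // 2
    for h in config.hotspots:
        if h.chrom == chrom:
            weight[(mid >= h.start) & (mid < h.end)] *= h.multiplier
    keep = np.ones(n_frag, bool)
    if which == "tumor":
        for c in config.cnvs:
            if c.chrom != chrom:
                continue
            if c.copy_ratio == 0.0:
                # homozygous deletion: drop every fragment whose span overlaps
                keep &= ~((starts < c.end) & (starts + inserts > c.start))
            else:
                weight[(mid >= c.start) & (mid < c.end)] *= c.copy_ratio
    thin = weight < 1.0
    if thin.any():
        u = rng.random(n_frag)
        keep &= ~thin | (u < weight)
    amp = weight > 1.0
    extra_s: list[np.ndarray] = []
    extra_i: list[np.ndarray] = []
    if amp.any():
        idx = np.flatnonzero(amp & keep)
        w = weight[idx] - 1.0
        n_dup = np.floor(w).astype(np.int64) + (rng.random(len(idx)) < (w % 1.0))
        rep = np.repeat(idx, n_dup)
        extra_s.append(starts[rep])
        extra_i.append(inserts[rep])
    starts = np.concatenate([starts[keep]] + extra_s)
    inserts = np.concatenate([inserts[keep]] + extra_i)
    return starts, inserts


def _simulate_sample(config: SimulationConfig, reference: dict[str, np.ndarray],
                     which: str) -> SimulatedSample:
    lengths = config.chrom_lengths()
    chrom_names = [c for c, _ in config.chromosomes]
    cid = {c: i for i, c in enumerate(chrom_names)}
    rl = config.read_length
    depth = config.normal_depth if which == "normal" else config.tumor_depth
    builders = {c: _Builder() for c in chrom_names}
    frag_counter = 0

    for chrom, length in config.chromosomes:
        starts, inserts = _fragment_placements(config, which, chrom, length)
        n = len(starts)
        fids = np.arange(frag_counter, frag_counter + n, dtype=np.int64)
        frag_counter += n

        disc = np.zeros(n, bool)
        if config.background_discordant_rate > 0 and len(chrom_names) > 1:
            rng = _rng(config.seed, which, "chimera", chrom)
            disc = rng.random(n) < config.background_discordant_rate
            didx = np.flatnonzero(disc)
            if len(didx):
                others = [c for c in chrom_names if c != chrom]
                mate_choice = rng.integers(0, len(others), size=len(didx))
                mate_pos = np.empty(len(didx), np.int64)
                for j, oc in enumerate(others):
                    sel = mate_choice == j
                    if sel.any():
                        mate_pos[sel] = rng.integers(0, lengths[oc] - rl, size=int(sel.sum()))
                # chimeric read on this chromosome
                for j, oc in enumerate(others):
                    sel = mate_choice == j
                    if not sel.any():
                        continue
                    rows = didx[sel]
                    builders[chrom].add(starts[rows], False, 0, cid[oc],
                                        mate_pos[sel], False, fids[rows], True)
                    builders[oc].add(mate_pos[sel], True, 0, cid[chrom],
                                     starts[rows], False, fids[rows], False)

        conc = ~disc
        s = starts[conc]
        ins = inserts[conc]
        f = fids[conc]
        r2start = s + ins - rl
        builders[chrom].add(s, False, ins, cid[chrom], r2start, True, f, True)
        builders[chrom].add(r2start, True, -ins, cid[chrom], s, True, f, False)

    for ti, t in enumerate(config.translocations):
        if t.origin == "somatic" and which == "normal":
            continue
        rng = _rng(config.seed, which, "tx", ti)
        n_pairs = t.n_pairs if t.n_pairs is not None else max(1, int(round(0.5 * depth)))
        fids = np.arange(frag_counter, frag_counter + n_pairs, dtype=np.int64)
        frag_counter += n_pairs
        lo_a = max(0, t.pos_a - 500)
        hi_a = min(lengths[t.chrom_a] - rl, t.pos_a)
        lo_b = min(t.pos_b, lengths[t.chrom_b] - rl)
        hi_b = min(t.pos_b + 500, lengths[t.chrom_b] - rl)
        pa = rng.integers(lo_a, max(lo_a + 1, hi_a + 1), size=n_pairs)
        pb = rng.integers(min(lo_b, hi_b), max(lo_b, hi_b) + 1, size=n_pairs)
        builders[t.chrom_a].add(pa, False, 0, cid[t.chrom_b], pb, False, fids, True)
        builders[t.chrom_b].add(pb, True, 0, cid[t.chrom_a], pa, False, fids, False)

    chroms: dict[str, ChromReads] = {}
    for chrom, length in config.chromosomes:
        chroms[chrom] = _materialise_chrom(config, reference, which, chrom,
                                           builders[chrom])
    return SimulatedSample(which, chrom_names, lengths, rl, chroms)


def _materialise_chrom(config: SimulationConfig, reference: dict[str, np.ndarray],
                       which: str, chrom: str, builder: _Builder) -> ChromReads:
    rl = config.read_length
    cols = builder.concat()
    order = np.argsort(cols["start"], kind="stable")
    cols = {k: v[order] for k, v in cols.items()}
    start = cols["start"]
    n = len(start)
    ref = reference[chrom]
    length = len(ref)
    offsets = np.arange(rl, dtype=np.int64)
    bases = ref[np.minimum(start[:, None] + offsets[None, :], length - 1)].copy()
    end = start + rl
    has_indel = np.zeros(n, bool)
    indel_ops: dict[int, tuple[IndelOp, ...]] = {}

    # --- indel planting (before SNVs: carrier reads leave the reference grid)
    for ii, ind in enumerate(config.indels):
        if ind.chrom != chrom:
            continue
        if ind.origin == "somatic":
            if which == "normal":
                continue
            frac = ind.vaf * config.cellularity
        else:
            frac = 1.0 if ind.zygosity == "hom" else 0.5
        # carrier must keep >=1 aligned query base on each side of the event
        if ind.kind == "del":
            lo_start = ind.start - rl + 1
        else:
            lo_start = ind.start - rl + ind.length + 1
        lo = np.searchsorted(start, lo_start, "left")
        hi = np.searchsorted(start, ind.start - 1, "right")
        rows = np.arange(lo, hi)
        rows = rows[~has_indel[rows]]
        if len(rows) == 0:
            continue
        rng = _rng(config.seed, which, "indel", ii)
        carriers = rows[rng.random(len(rows)) < frac]
        for r in carriers:
            s = int(start[r])
            if ind.kind == "del":
                d = ind.start
                k = ind.length
                if s + rl + k > length:
                    continue
                seg = np.concatenate([ref[s:d], ref[d + k:s + rl + k]])
                op = IndelOp(d, "del", k,
                             decode_seq(ref[d:d + k]))
                end[r] = s + rl + k
            else:
                d = ind.start
                k = ind.length
                ins_codes = _encode(ind.sequence)
                seg = np.concatenate([ref[s:d], ins_codes, ref[d:s + rl - k]])
                op = IndelOp(d, "ins", k, ind.sequence.upper())
                end[r] = s + rl - k
            bases[r, :] = seg[:rl]
            has_indel[r] = True
            indel_ops[int(r)] = (op,)

    # --- SNV planting on reads still on the reference grid
    for si, snv in enumerate(config.snvs):
        if snv.chrom != chrom:
            continue
        if snv.origin == "somatic":
            if which == "normal":
                continue
            frac = snv.vaf * config.cellularity
        else:
            frac = 1.0 if snv.zygosity == "hom" else 0.5
        lo = np.searchsorted(start, snv.pos - rl + 1, "left")
        hi = np.searchsorted(start, snv.pos, "right")
        rows = np.arange(lo, hi)
        rows = rows[~has_indel[rows]]
        if len(rows) == 0:
            continue
        rng = _rng(config.seed, which, "snv", si)
        carriers = rows[rng.random(len(rows)) < frac]
        bases[carriers, snv.pos - start[carriers]] = _CODE[snv.alt]

    # --- qualities, zero-quality bases, miscalls
    rngq = _rng(config.seed, which, "quals", chrom)
    quals = np.clip(np.round(rngq.normal(config.base_quality_mean,
                                         config.base_quality_sd,
                                         size=bases.shape)), 2, 41).astype(np.uint8)
    if config.zero_quality_fraction > 0:
        zq = rngq.random(bases.shape) < config.zero_quality_fraction
        quals[zq] = 0
    rnge = _rng(config.seed, which, "errors", chrom)
    p_err = _ERR_LUT[quals]
    mis = rnge.random(bases.shape) < p_err
    k = int(mis.sum())
    if k:
        bases[mis] = (bases[mis] + rnge.integers(1, 4, size=k).astype(np.uint8)) % 4

    return ChromReads(
        chrom=chrom,
        start=start,
        is_reverse=cols["is_reverse"],
        bases=bases,
        quals=quals,
        tlen=cols["tlen"],
        end=end,
        mate_chrom_id=cols["mate_chrom_id"],
        mate_pos=cols["mate_pos"],
        proper=cols["proper"],
        frag_id=cols["frag_id"],
        is_read1=cols["is_read1"],
        has_indel=has_indel,
        indel_ops=indel_ops,
    )


# ---------------------------------------------------------------------------
# per-locus aggregation for the SNV caller
# ---------------------------------------------------------------------------

def base_count_arrays(sample: SimulatedSample, chrom: str, chunk: int = 200_000):
    """Trimmed per-strand base counts and error-probability sums per locus.

    Returns ``(counts, err_sum)`` where ``counts`` has shape (2, L, 4)
    (strand 0 = forward) holding quality-trimmed base counts, and ``err_sum``
    has shape (2, L) holding the sum of per-base miscall probabilities
    ``10^(-Q/10)`` of the counted bases.  Reads carrying indel operations are
    excluded (their bases after the event are not on the reference grid).
    """
    cr = sample.chroms[chrom]
    L = sample.chrom_lengths[chrom]
    rl = sample.read_length
    counts = np.zeros((2, L * 4), np.int64)
    err_sum = np.zeros((2, L), np.float64)
    offsets = np.arange(rl, dtype=np.int64)
    for strand, rev in ((0, False), (1, True)):
        rows = np.flatnonzero((cr.is_reverse == rev) & ~cr.has_indel)
        for i in range(0, len(rows), chunk):
            sel = rows[i:i + chunk]
            pos = cr.start[sel][:, None] + offsets[None, :]
            valid = (pos < L) & (cr.quals[sel] > 0)
            flat_pos = pos[valid]
            b = cr.bases[sel][valid]
            q = cr.quals[sel][valid]
            counts[strand] += np.bincount(flat_pos * 4 + b, minlength=L * 4)
            err_sum[strand] += np.bincount(flat_pos, weights=_ERR_LUT[q],
                                           minlength=L)
    return counts.reshape(2, L, 4), err_sum


def pileup_columns(sample: SimulatedSample, reference: dict[str, np.ndarray],
                   loci: Iterable[tuple[str, int]]) -> list[PileupColumn]:
    """Raw (untrimmed) pileup columns at the given 0-based loci."""
    out = []
    rl = sample.read_length
    for chrom, pos in loci:
        cr = sample.chroms[chrom]
        lo = np.searchsorted(cr.start, pos - rl + 1, "left")
        hi = np.searchsorted(cr.start, pos, "right")
        rows = np.arange(lo, hi)
        rows = rows[(cr.start[rows] <= pos) & (pos < cr.start[rows] + rl)
                    & ~cr.has_indel[rows]]
        fwd: list[tuple[str, int]] = []
        rev: list[tuple[str, int]] = []
        for r in rows:
            col = pos - int(cr.start[r])
            entry = (BASES[cr.bases[r, col]], int(cr.quals[r, col]))
            (rev if cr.is_reverse[r] else fwd).append(entry)
        out.append(PileupColumn(chrom, pos + 1, BASES[reference[chrom][pos]],
                                fwd, rev))
    return out


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def _cigar_for_read(rl: int, start: int, ops: tuple[IndelOp, ...]):
    if not ops:
        return [(0, rl)]
    cigar = []
    q = 0
    ref_cursor = start
    for op in sorted(ops, key=lambda o: o.start):
        m = op.start - ref_cursor
        if m > 0:
            cigar.append((0, m))
            q += m
        if op.kind == "del":
            cigar.append((2, op.length))
            ref_cursor = op.start + op.length
        else:
            cigar.append((1, op.length))
            q += op.length
            ref_cursor = op.start
    if q < rl:
        cigar.append((0, rl - q))
    return cigar


def emit_alignments(sample: SimulatedSample, path: str) -> None:
    """Write the sample as a coordinate-sorted SAM file (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": sample.chrom_lengths[c]} for c in sample.chrom_names],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for chrom in sample.chrom_names:
            cr = sample.chroms.get(chrom)
            if cr is None:
                continue
            if len(cr) and np.any(np.diff(cr.start) < 0):
                raise ValueError(f"reads on {chrom} are not coordinate sorted")
            for i in range(len(cr)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"frag{int(cr.frag_id[i])}"
                a.reference_id = out.header.references.index(chrom)
                a.reference_start = int(cr.start[i])
                a.mapping_quality = 60
                flag = 0x1  # paired
                if cr.proper[i]:
                    flag |= 0x2
                if cr.is_reverse[i]:
                    flag |= 0x10
                else:
                    flag |= 0x20  # mate on reverse strand for FR pairs
                flag |= 0x40 if cr.is_read1[i] else 0x80
                a.flag = flag
                a.cigartuples = _cigar_for_read(sample.read_length,
                                                int(cr.start[i]),
                                                cr.indel_ops.get(i, ()))
                a.query_sequence = decode_seq(cr.bases[i])
                a.query_qualities = cr.quals[i].tolist()
                mid = int(cr.mate_chrom_id[i])
                a.next_reference_id = mid
                a.next_reference_start = int(cr.mate_pos[i])
                a.template_length = int(cr.tlen[i])
                out.write(a)


def emit_pileups(sample: SimulatedSample, reference: dict[str, np.ndarray],
                 path: str) -> None:
    """Write the documented per-locus pileup TSV.

    Columns: chrom, 1-based position, reference base, forward base string,
    forward phred string (ASCII offset 33), reverse base string, reverse
    phred string.  Only loci covered by at least one read are emitted.
    Reads carrying indel operations are excluded.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\tfwd_bases\tfwd_quals\trev_bases\trev_quals\n")
        for chrom in sample.chrom_names:
            cr = sample.chroms.get(chrom)
            if cr is None or len(cr) == 0:
                continue
            L = sample.chrom_lengths[chrom]
            cov = np.zeros(L + 1, np.int32)
            rows_ok = np.flatnonzero(~cr.has_indel)
            np.add.at(cov, cr.start[rows_ok], 1)
            np.add.at(cov, np.minimum(cr.start[rows_ok] + sample.read_length, L), -1)
            cov = np.cumsum(cov[:-1])
            for pos in np.flatnonzero(cov > 0):
                col = pileup_columns(sample, reference, [(chrom, int(pos))])[0]
                fh.write("\t".join([
                    chrom, str(int(pos) + 1), col.ref,
                    "".join(b for b, _ in col.fwd) or "*",
                    "".join(chr(q + 33) for _, q in col.fwd) or "*",
                    "".join(b for b, _ in col.rev) or "*",
                    "".join(chr(q + 33) for _, q in col.rev) or "*",
                ]) + "\n")


def read_pileup_tsv(path: str) -> list[PileupColumn]:
    """Read the documented pileup TSV back into columns."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, ref, fb, fq, rb, rq = line.rstrip("\n").split("\t")
            fwd = [] if fb == "*" else [(b, ord(c) - 33) for b, c in zip(fb, fq)]
            rev = [] if rb == "*" else [(b, ord(c) - 33) for b, c in zip(rb, rq)]
            out.append(PileupColumn(chrom, int(pos), ref, fwd, rev))
    return out


def write_truth(truth: TruthSet, outdir: str,
                reference: dict[str, np.ndarray] | None = None) -> dict[str, str]:
    """Write truth VCF (SNVs+indels), BED (CNV) and BEDPE (translocations)."""
    import os

    truth.validate()
    paths = {
        "vcf": os.path.join(outdir, "truth.vcf"),
        "bed": os.path.join(outdir, "truth_cnv.bed"),
        "bedpe": os.path.join(outdir, "truth_tx.bedpe"),
    }
    recs: list[tuple[str, int, str, str, str]] = []
    for s in truth.snvs:
        info = f"ORIGIN={s.origin};VAF={s.vaf:g};EVENT=snv"
        recs.append((s.chrom, s.pos, s.ref, s.alt, info))
    for ind in truth.indels:
        info = f"ORIGIN={ind.origin};VAF={ind.vaf:g};EVENT={ind.kind};SVLEN={len(ind.sequence)}"
        if reference is not None:
            anchor_pos = ind.start - 1
            anchor = BASES[reference[ind.chrom][anchor_pos]]
            if ind.kind == "del":
                recs.append((ind.chrom, anchor_pos, anchor + ind.sequence, anchor, info))
            else:
                recs.append((ind.chrom, anchor_pos, anchor, anchor + ind.sequence, info))
        else:
            alt = "<DEL>" if ind.kind == "del" else "<INS>"
            recs.append((ind.chrom, ind.start, "N", alt, info))
    recs.sort(key=lambda r: (r[0], r[1]))
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="germline or somatic">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Spiked variant allele fraction">\n')
        fh.write('##INFO=<ID=EVENT,Number=1,Type=String,Description="snv, ins or del">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Indel length">\n')
        if reference is not None:
            for chrom in reference:
                fh.write(f"##contig=<ID={chrom},length={len(reference[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt, info in recs:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
    with open(paths["bed"], "w") as fh:
        for c in truth.cnv_segments:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tratio={c.copy_ratio:g}\n")
    with open(paths["bedpe"], "w") as fh:
        for t in truth.translocations:
            fh.write(f"{t.chrom_a}\t{t.pos_a}\t{t.pos_a + 1}\t"
                     f"{t.chrom_b}\t{t.pos_b}\t{t.pos_b + 1}\t"
                     f"tx\t.\t+\t+\t{t.origin}\n")
    return paths


# ---------------------------------------------------------------------------
# spike placement helper
# ---------------------------------------------------------------------------

def random_sites(rng: np.random.Generator, chromosomes: Sequence[tuple[str, int]],
                 n: int, margin: int = 500, min_spacing: int = 50,
                 exclude: Iterable[tuple[str, int]] = ()) -> list[tuple[str, int]]:
    """Draw n distinct (chrom, pos) sites, away from chromosome ends and
    at least ``min_spacing`` bp from each other and from ``exclude``."""
    taken: dict[str, list[int]] = {}
    for chrom, pos in exclude:
        taken.setdefault(chrom, []).append(pos)
    total = sum(l for _, l in chromosomes)
    sites: list[tuple[str, int]] = []
    attempts = 0
    while len(sites) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not place spike sites; genome too small")
        u = rng.random() * total
        acc = 0
        for chrom, length in chromosomes:
            if u < acc + length:
                pos = int(rng.integers(margin, max(margin + 1, length - margin)))
                near = taken.get(chrom, [])
                if all(abs(pos - p) >= min_spacing for p in near):
                    sites.append((chrom, pos))
                    taken.setdefault(chrom, []).append(pos)
                break
            acc += length
    return sites
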