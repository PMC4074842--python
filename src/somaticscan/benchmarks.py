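"""Seeded benchmark scenarios and their metric runners.

Each ``*_benchmark`` function builds a simulation configuration encoding the
study conditions a detector is evaluated under (sample depths, cellularity,
event counts and sizes), and each ``run_*`` function executes the detector
on a fresh simulation and measures precision/recall or the relevant signal
level against the truth set.  Problem sizes are chosen so every scenario
runs in minutes on one CPU: megabase-scale chromosomes at 40x rather than a
full genome — large enough for stable window statistics and binomial allele
fractions, small enough to iterate on.

The same runners back the test suite and the reproduction script, so every
reported number is recomputed from scratch.
"""

from __future__ import annotations

import math
import tempfile
from typing import Sequence

import numpy as np

from . import cnvscan, indelsom, simdata as sd, txscan
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "snv_benchmark", "cnv_benchmark", "indel_benchmark", "tx_benchmark",
    "tx_null_benchmark", "compact_scenario",
    "run_snv_benchmark", "run_cnv_benchmark", "run_indel_benchmark",
    "run_tx_benchmark", "run_tx_null_benchmark", "run_determinism_check",
]


def _seed(base: int, label: int) -> int:
    return (int(base) * 1009 + label) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def snv_benchmark(seed: int):
    """Somatic SNV recovery conditions: two 2 Mb chromosomes at 40x/40x,
    cellularity 0.6, 100 somatic SNVs with VAF uniform on [0.3, 1] and
    200 germline heterozygous SNPs."""
    chroms = [("chr1", 2_000_000), ("chr2", 2_000_000)]
    sim_seed = _seed(seed, 1)
    # the reference depends only on (chromosomes, seed), so spiked alts chosen
    # here stay consistent when the pipeline regenerates it from the config
    ref = sd.simulate_reference(sd.SimulationConfig(chromosomes=chroms,
                                                    seed=sim_seed))
    rng = np.random.default_rng(_seed(seed, 2))
    sites = sd.random_sites(rng, chroms, 300, min_spacing=300)
    snvs = []
    for i, (c, p) in enumerate(sites):
        alt = "ACGT"[(int(ref[c][p]) + 1 + int(rng.integers(0, 3))) % 4]
        if i < 100:
            snvs.append(sd.SnvSpike(c, p, alt, vaf=float(rng.uniform(0.3, 1.0)),
                                    origin="somatic"))
        else:
            snvs.append(sd.SnvSpike(c, p, alt, origin="germline", zygosity="het"))
    config = sd.SimulationConfig(chromosomes=chroms, seed=sim_seed,
                                 cellularity=0.6, normal_depth=40, tumor_depth=40,
                                 snvs=snvs)
    return config, ref


def cnv_benchmark(seed: int):
    """CNV conditions: two 1 Mb chromosomes at 40x, one copy-ratio-2 gain
    over 100 kb (5% of the genome), one 50 kb homozygous deletion and one
    20 kb x12 coverage hotspot (high-repeat stand-in)."""
    chroms = [("chr1", 1_000_000), ("chr2", 1_000_000)]
    ref = sd.simulate_reference(sd.SimulationConfig(chromosomes=chroms,
                                                    seed=_seed(seed, 11)))
    config = sd.SimulationConfig(
        chromosomes=chroms, seed=_seed(seed, 12), normal_depth=40, tumor_depth=40,
        cnvs=[sd.CnvSpike("chr1", 300_000, 400_000, 2.0),
              sd.CnvSpike("chr2", 500_000, 550_000, 0.0)],
        hotspots=[sd.HotspotSpike("chr1", 700_000, 720_000, 12.0)])
    return config, ref


def indel_benchmark(seed: int):
    """Indel conditions: one 1 Mb chromosome at 40x, cellularity 0.6,
    24 somatic indels of lengths 1-10 bp (VAF 0.5) plus 10 germline hets."""
    chroms = [("chr1", 1_000_000)]
    ref = sd.simulate_reference(sd.SimulationConfig(chromosomes=chroms,
                                                    seed=_seed(seed, 21)))
    rng = np.random.default_rng(_seed(seed, 22))
    sites = sd.random_sites(rng, chroms, 34, min_spacing=2000)
    indels = []
    for i, (c, p) in enumerate(sites):
        length = 1 + (i % 10)
        kind = "del" if i % 2 == 0 else "ins"
        seq = "".join("ACGT"[j] for j in rng.integers(0, 4, length)) if kind == "ins" else ""
        origin = "somatic" if i < 24 else "germline"
        indels.append(sd.IndelSpike(c, p, kind, length, sequence=seq,
                                    vaf=0.5, origin=origin))
    config = sd.SimulationConfig(chromosomes=chroms, seed=_seed(seed, 23),
                                 cellularity=0.6, normal_depth=40, tumor_depth=40,
                                 indels=indels)
    return config, ref


def tx_benchmark(seed: int):
    """Translocation conditions: three 1 Mb chromosomes at 40x with the
    default 0.1% chimera background, two somatic events and one germline
    event (present in both samples)."""
    chroms = [("chr1", 1_000_000), ("chr2", 1_000_000), ("chr3", 1_000_000)]
    ref = sd.simulate_reference(sd.SimulationConfig(chromosomes=chroms,
                                                    seed=_seed(seed, 31)))
    config = sd.SimulationConfig(
        chromosomes=chroms, seed=_seed(seed, 32), normal_depth=40, tumor_depth=40,
        translocations=[
            sd.TxSpike("chr1", 250_000, "chr2", 700_000, origin="somatic"),
            sd.TxSpike("chr2", 150_000, "chr3", 400_000, origin="somatic"),
            sd.TxSpike("chr1", 800_000, "chr3", 900_000, origin="germline"),
        ])
    return config, ref


def tx_null_benchmark(seed: int):
    """Null conditions: two 400 kb chromosomes at 10x, chimera background
    only, no spiked events."""
    chroms = [("chr1", 400_000), ("chr2", 400_000)]
    ref = sd.simulate_reference(sd.SimulationConfig(chromosomes=chroms,
                                                    seed=_seed(seed, 41)))
    config = sd.SimulationConfig(chromosomes=chroms, seed=_seed(seed, 42),
                                 normal_depth=10, tumor_depth=10)
    return config, ref


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def run_snv_benchmark(seed: int, outdir: str | None = None) -> dict:
    config, ref = snv_benchmark(seed)
    with tempfile.TemporaryDirectory() as tmp:
        pc = PipelineConfig(output_dir=outdir or tmp, simulation=config,
                            snv_profile="lenient")
        bundle = run_pipeline(pc, only=("snv",))
    truth = bundle.truth
    m = bundle.report.classes["snv"]
    germline_loci = {(t.chrom, t.pos + 1) for t in truth.snvs
                     if t.origin == "germline"}
    leak = sum(1 for c in bundle.snv_calls if (c.chrom, c.pos) in germline_loci)
    return {
        "precision": m.precision, "recall": m.recall,
        "tp": m.tp, "fp": m.fp, "fn": m.fn,
        "germline_leak": leak,
        "n_somatic_truth": sum(1 for t in truth.snvs if t.origin == "somatic"),
        "n_germline_truth": len(germline_loci),
    }


def _windows_inside(windows: Sequence[cnvscan.CoverageWindow], chrom: str,
                    start: int, end: int) -> list[cnvscan.CoverageWindow]:
    return [w for w in windows
            if w.chrom == chrom and w.start >= start and w.end <= end]


def run_cnv_benchmark(seed: int) -> dict:
    config, ref = cnv_benchmark(seed)
    normal, tumor, truth = sd.simulate_pair(config, ref)
    n_table = normal.to_read_table()
    t_table = tumor.to_read_table()
    lengths = config.chrom_lengths()
    params = cnvscan.CnvParams()
    windows, segments = cnvscan.scan_cnv(n_table, t_table, lengths, params)

    # identity check: the normal sample against itself
    id_windows, id_segments = cnvscan.scan_cnv(n_table, n_table, lengths, params)
    id_ratios = [w.log2_ratio for w in id_windows if not w.masked]
    identity_max_abs = float(max(abs(r) for r in id_ratios))

    gain = next(t for t in truth.cnv_segments if t.copy_ratio > 1)
    homdel = next(t for t in truth.cnv_segments if t.copy_ratio == 0)
    gain_segs = [s for s in segments if s.direction == "gain"
                 and s.chrom == gain.chrom
                 and min(s.end, gain.end) > max(s.start, gain.start)]
    gain_mean = (float(np.average([s.mean_log2 for s in gain_segs],
                                  weights=[s.window_count for s in gain_segs]))
                 if gain_segs else float("nan"))
    homdel_win = _windows_inside(windows, homdel.chrom, homdel.start, homdel.end)
    homdel_mean = float(np.mean([w.log2_ratio for w in homdel_win
                                 if not w.masked]))
    ratios = [w.log2_ratio for w in windows if not w.masked]
    all_finite = bool(np.all(np.isfinite(ratios))) and bool(
        np.all(np.isfinite([w.log2_ratio for w in id_windows if not w.masked])))
    mask_consistent = all(
        w.masked == (math.log2(w.normal_norm) > params.repeat_mask_log2)
        for w in windows)
    return {
        "identity_max_abs_log2": identity_max_abs,
        "identity_segments": len(id_segments),
        "gain_segment_found": bool(gain_segs),
        "gain_mean_log2": gain_mean,
        "homdel_mean_log2": homdel_mean,
        "all_ratios_finite": all_finite,
        "masked_windows": sum(w.masked for w in windows),
        "mask_consistent": mask_consistent,
        "n_windows": len(windows),
    }


def run_indel_benchmark(seed: int) -> dict:
    from .pipeline import evaluate_against_truth

    config, ref = indel_benchmark(seed)
    normal, tumor, truth = sd.simulate_pair(config, ref)
    params = indelsom.IndelParams()
    candidates = indelsom.call_somatic_indels(tumor.to_read_table(),
                                              normal.to_read_table(), params)
    report = evaluate_against_truth(truth, indel_calls=candidates,
                                    indel_tolerance=params.flank)
    m = report.classes["indel"]
    germline_flagged = 0
    for t in truth.indels:
        if t.origin != "germline":
            continue
        for c in candidates:
            if (c.status == "somatic" and c.chrom == t.chrom and c.kind == t.kind
                    and abs(c.start - t.start) <= params.flank):
                germline_flagged += 1
    return {
        "precision": m.precision, "recall": m.recall,
        "tp": m.tp, "fp": m.fp, "fn": m.fn,
        "germline_flagged_somatic": germline_flagged,
        "n_somatic_truth": sum(1 for t in truth.indels if t.origin == "somatic"),
    }


def _breakpoint_error(call: txscan.TranslocationCall, t: sd.TruthTx) -> float:
    def dist(region, pos):
        if region[1] <= pos < region[2]:
            return 0.0
        return min(abs(pos - region[1]), abs(pos - (region[2] - 1)))

    fwd = max(dist(call.region_a(), t.pos_a), dist(call.region_b(), t.pos_b)) \
        if (call.chrom_a == t.chrom_a and call.chrom_b == t.chrom_b) else math.inf
    rev = max(dist(call.region_a(), t.pos_b), dist(call.region_b(), t.pos_a)) \
        if (call.chrom_a == t.chrom_b and call.chrom_b == t.chrom_a) else math.inf
    return min(fwd, rev)


def run_tx_benchmark(seed: int) -> dict:
    config, ref = tx_benchmark(seed)
    normal, tumor, truth = sd.simulate_pair(config, ref)
    params = txscan.TxParams()
    t_table = tumor.to_read_table()
    n_table = normal.to_read_table()
    somatic_calls, _ = txscan.scan_translocations(t_table, n_table, params)
    tumor_only_calls, _ = txscan.scan_translocations(t_table, None, params)

    somatic_truth = [t for t in truth.translocations if t.origin == "somatic"]
    germline_truth = [t for t in truth.translocations if t.origin == "germline"]

    def recovered(calls, truths, tol=2000):
        hits, errs = 0, []
        for t in truths:
            best = min((_breakpoint_error(c, t) for c in calls), default=math.inf)
            if best <= tol:
                hits += 1
                errs.append(best)
        return hits, errs

    som_hits, som_errs = recovered(somatic_calls, somatic_truth)
    tum_hits, _ = recovered(tumor_only_calls, somatic_truth)
    germ_hits, _ = recovered(somatic_calls, germline_truth)
    return {
        "somatic_truth": len(somatic_truth),
        "recovered_somatic": som_hits,
        "recovered_tumor_only": tum_hits,
        "max_breakpoint_error": float(max(som_errs)) if som_errs else float("nan"),
        "germline_in_somatic_output": germ_hits,
        "n_somatic_calls": len(somatic_calls),
    }


def compact_scenario(seed: int, chrom_len: int = 200_000, n_somatic: int = 10,
                     n_germline: int = 10, cellularity: float = 0.6,
                     vaf: float = 0.5, depth: float = 40.0):
    """Small two-chromosome scenario carrying every event class at once:
    SNVs, indels, a gain, a homozygous deletion, a translocation and a
    coverage hotspot.  Used for end-to-end and determinism checks."""
    chroms = [("chr1", chrom_len), ("chr2", chrom_len)]
    sim_seed = _seed(seed, 51)
    ref = sd.simulate_reference(sd.SimulationConfig(chromosomes=chroms,
                                                    seed=sim_seed))
    rng = np.random.default_rng(_seed(seed, 52))
    u = chrom_len // 20
    # keep SNV sites out of the homozygous deletion (no tumor DNA there)
    sites: list[tuple[str, int]] = []
    while len(sites) < n_somatic + n_germline:
        (c, p), = sd.random_sites(rng, chroms, 1, min_spacing=300,
                                  exclude=sites)
        if c == "chr2" and 10 * u - 500 <= p < 13 * u + 500:
            continue
        sites.append((c, p))
    snvs = []
    for i, (c, p) in enumerate(sites):
        alt = "ACGT"[(int(ref[c][p]) + 1) % 4]
        origin = "somatic" if i < n_somatic else "germline"
        snvs.append(sd.SnvSpike(c, p, alt, vaf=vaf, origin=origin))
    config = sd.SimulationConfig(
        chromosomes=chroms, seed=sim_seed, cellularity=cellularity,
        normal_depth=depth, tumor_depth=depth, snvs=snvs,
        indels=[sd.IndelSpike("chr1", 5 * u, "del", 3, origin="somatic", vaf=vaf),
                sd.IndelSpike("chr2", 6 * u, "ins", 4, sequence="ACGT",
                              origin="germline")],
        cnvs=[sd.CnvSpike("chr1", 10 * u, 14 * u, 2.0),
              sd.CnvSpike("chr2", 10 * u, 13 * u, 0.0)],
        translocations=[sd.TxSpike("chr1", 17 * u, "chr2", 3 * u,
                                   origin="somatic")],
        hotspots=[sd.HotspotSpike("chr2", 16 * u, 17 * u, 12.0)])
    return config, ref


def run_determinism_check(seed: int) -> dict:
    """Run the full pipeline twice under one seed and byte-compare outputs."""
    import filecmp
    import os

    config, _ = compact_scenario(seed, chrom_len=100_000)
    digests = []
    with tempfile.TemporaryDirectory() as tmp:
        names = None
        for run in ("a", "b"):
            outdir = os.path.join(tmp, run)
            pc = PipelineConfig(output_dir=outdir, simulation=config)
            bundle = run_pipeline(pc)
            files = sorted(os.path.basename(p) for p in bundle.paths.values())
            if names is None:
                names = files
            assert files == names
            digests.append(outdir)
        identical = all(
            filecmp.cmp(os.path.join(digests[0], f), os.path.join(digests[1], f),
                        shallow=False)
            for f in names)
    return {"identical": identical, "n_files": len(names)}


def run_tx_null_benchmark(seed: int, replicates: int = 20) -> dict:
    zero = 0
    params = txscan.TxParams()
    for i in range(replicates):
        config, ref = tx_null_benchmark(_seed(seed, 100 + i))
        _, tumor, _ = sd.simulate_pair(config, ref)
        calls, _ = txscan.scan_translocations(tumor.to_read_table(), None, params)
        if not calls:
            zero += 1
    return {"replicates": replicates, "zero_call_replicates": zero,
            "zero_call_fraction": zero / replicates}
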