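"""Tests of the tumor/normal read simulator's statistical contracts."""

import numpy as np
import pytest
from scipy.stats import binom, truncnorm

from somaticscan import simdata as sd
from somaticscan.records import read_table_from_sam


def base_config(**kw):
    defaults = dict(chromosomes=[("chr1", 50_000)], seed=11)
    defaults.update(kw)
    return sd.SimulationConfig(**defaults)


class TestReference:
    def test_declared_lengths_and_alphabet(self):
        cfg = base_config(chromosomes=[("chr1", 1000), ("chr2", 2000)])
        ref = sd.simulate_reference(cfg)
        assert len(ref["chr1"]) == 1000 and len(ref["chr2"]) == 2000
        assert set(np.unique(ref["chr1"])) <= {0, 1, 2, 3}

    def test_deterministic_under_seed(self):
        cfg = base_config(chromosomes=[("chr1", 1000)])
        a = sd.simulate_reference(cfg)
        b = sd.simulate_reference(cfg)
        assert np.array_equal(a["chr1"], b["chr1"])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            base_config(chromosomes=[("chr1", 0)])
            sd.SimulationConfig(chromosomes=[("chr1", 0)]).validate()


class TestConfigValidation:
    def test_spike_outside_reference(self):
        with pytest.raises(ValueError, match="outside"):
            base_config(snvs=[sd.SnvSpike("chr1", 60_000, "A")]).validate()

    def test_cellularity_bounds(self):
        with pytest.raises(ValueError, match="cellularity"):
            base_config(cellularity=0.0).validate()

    def test_overlapping_cnvs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            base_config(cnvs=[sd.CnvSpike("chr1", 0, 2000, 2.0),
                              sd.CnvSpike("chr1", 1000, 3000, 0.5)]).validate()

    def test_intrachromosomal_translocation_rejected(self):
        with pytest.raises(ValueError, match="interchromosomal"):
            base_config(translocations=[
                sd.TxSpike("chr1", 1000, "chr1", 30_000)]).validate()


class TestSamplingModel:
    def test_identical_seed_identical_reads(self):
        cfg = base_config()
        ref = sd.simulate_reference(cfg)
        n1, t1, _ = sd.simulate_pair(cfg, ref)
        n2, t2, _ = sd.simulate_pair(cfg, ref)
        for a, b in ((n1, n2), (t1, t2)):
            ca, cb = a.chroms["chr1"], b.chroms["chr1"]
            assert np.array_equal(ca.start, cb.start)
            assert np.array_equal(ca.bases, cb.bases)
            assert np.array_equal(ca.quals, cb.quals)
            assert np.array_equal(ca.tlen, cb.tlen)

    def test_depth_calibration_megabase(self):
        cfg = base_config(chromosomes=[("chr1", 1_000_000)], normal_depth=20,
                          tumor_depth=20, seed=5)
        ref = sd.simulate_reference(cfg)
        normal, tumor, _ = sd.simulate_pair(cfg, ref)
        for sample in (normal, tumor):
            realized = sample.n_reads() * cfg.read_length / 1_000_000
            assert realized == pytest.approx(20.0, rel=0.05)

    def test_insert_sizes_match_truncated_normal(self):
        cfg = base_config(chromosomes=[("chr1", 500_000)], normal_depth=20,
                          insert_mean=300, insert_sd=50, seed=6)
        ref = sd.simulate_reference(cfg)
        normal, _, _ = sd.simulate_pair(cfg, ref)
        table = normal.to_read_table()
        inserts = table.insert[table.proper & (table.insert > 0)].astype(float)
        lo = 2 * cfg.read_length
        a = (lo - cfg.insert_mean) / cfg.insert_sd
        mu, var = truncnorm.stats(a, np.inf, loc=cfg.insert_mean,
                                  scale=cfg.insert_sd, moments="mv")
        se_mean = np.sqrt(var / len(inserts))
        assert abs(inserts.mean() - mu) < 3 * se_mean + 0.5  # 0.5 for rounding
        assert np.std(inserts, ddof=1) == pytest.approx(np.sqrt(var), rel=0.05)

    def test_purity_dilution_over_many_snvs(self):
        """Mean observed somatic alt fraction ~ VAF x cellularity (3 SE)."""
        chroms = [("chr1", 200_000)]
        cfg0 = sd.SimulationConfig(chromosomes=chroms, seed=13)
        ref = sd.simulate_reference(cfg0)
        rng = np.random.default_rng(1)
        sites = sd.random_sites(rng, chroms, 60, min_spacing=400)
        snvs = [sd.SnvSpike(c, p, "ACGT"[(int(ref[c][p]) + 1) % 4],
                            vaf=0.5, origin="somatic") for c, p in sites]
        cfg = sd.SimulationConfig(chromosomes=chroms, seed=13, cellularity=0.5,
                                  normal_depth=40, tumor_depth=40, snvs=snvs)
        _, tumor, truth = sd.simulate_pair(cfg, ref)
        alt_total = depth_total = 0
        for t, col in zip(truth.snvs,
                          sd.pileup_columns(tumor, ref,
                                            [(t.chrom, t.pos) for t in truth.snvs])):
            entries = col.fwd + col.rev
            alt_total += sum(1 for b, q in entries if b == t.alt and q > 0)
            depth_total += sum(1 for _, q in entries if q > 0)
        p_exp = 0.5 * 0.5
        se = np.sqrt(p_exp * (1 - p_exp) / depth_total)
        assert abs(alt_total / depth_total - p_exp) < 3 * se + 0.005

    def test_single_snv_within_binomial_99_interval(self):
        """Full-purity VAF-0.5 SNV: tumor alt count inside the binomial 99%
        interval; normal alt count inside the 99% interval of the error rate."""
        chroms = [("chr1", 100_000)]
        cfg0 = sd.SimulationConfig(chromosomes=chroms, seed=21)
        ref = sd.simulate_reference(cfg0)
        pos = 50_000
        alt = "ACGT"[(int(ref["chr1"][pos]) + 1) % 4]
        cfg = sd.SimulationConfig(chromosomes=chroms, seed=21, cellularity=1.0,
                                  normal_depth=60, tumor_depth=60,
                                  snvs=[sd.SnvSpike("chr1", pos, alt, vaf=0.5)])
        normal, tumor, _ = sd.simulate_pair(cfg, ref)
        tcol = sd.pileup_columns(tumor, ref, [("chr1", pos)])[0]
        entries = [(b, q) for b, q in tcol.fwd + tcol.rev if q > 0]
        n = len(entries)
        k = sum(1 for b, _ in entries if b == alt)
        assert binom.ppf(0.005, n, 0.5) <= k <= binom.ppf(0.995, n, 0.5)
        ncol = sd.pileup_columns(normal, ref, [("chr1", pos)])[0]
        nentries = [(b, q) for b, q in ncol.fwd + ncol.rev if q > 0]
        e = np.mean([10 ** (-q / 10) for _, q in nentries])
        k_norm = sum(1 for b, _ in nentries if b != ncol.ref)
        assert k_norm <= binom.ppf(0.995, len(nentries), max(e, 1e-3))

    def test_het_snp_shows_both_alleles_at_depth_40(self):
        cfg0 = base_config(seed=19)
        ref = sd.simulate_reference(cfg0)
        pos = 25_000
        alt = "ACGT"[(int(ref["chr1"][pos]) + 1) % 4]
        cfg = base_config(seed=19, normal_depth=40, tumor_depth=40,
                          snvs=[sd.SnvSpike("chr1", pos, alt, origin="germline",
                                            zygosity="het")])
        normal, _, _ = sd.simulate_pair(cfg, ref)
        col = sd.pileup_columns(normal, ref, [("chr1", pos)])[0]
        bases = {b for b, _ in col.fwd + col.rev}
        assert {col.ref, alt} <= bases

    def test_homozygous_deletion_has_no_tumor_fragments(self):
        seg = (20_000, 30_000)
        cfg = base_config(cnvs=[sd.CnvSpike("chr1", *seg, 0.0)])
        ref = sd.simulate_reference(cfg)
        _, tumor, _ = sd.simulate_pair(cfg, ref)
        table = tumor.to_read_table()
        pairs = table.proper & (table.insert > 0)
        start = table.start[pairs]
        end = start + table.insert[pairs]
        assert not np.any((start < seg[1]) & (end > seg[0]))

    def test_vaf_cellularity_product_is_the_expected_fraction(self):
        s = sd.SnvSpike("chr1", 10, "A", vaf=0.5, origin="somatic")
        assert s.vaf * 0.5 == pytest.approx(0.25)


class TestEmission:
    def test_single_fragment_pileup_depth_one(self, tmp_path):
        cfg = sd.SimulationConfig(chromosomes=[("chr1", 1000)], seed=23,
                                  normal_depth=0.2, tumor_depth=0.2,
                                  insert_mean=300, insert_sd=0,
                                  zero_quality_fraction=0.0,
                                  background_discordant_rate=0.0)
        ref = sd.simulate_reference(cfg)
        normal, _, _ = sd.simulate_pair(cfg, ref)
        assert normal.n_reads() == 2
        path = tmp_path / "pileup.tsv"
        sd.emit_pileups(normal, ref, str(path))
        cols = sd.read_pileup_tsv(str(path))
        assert len(cols) == 200  # two 100 bp read segments
        assert all(c.depth == 1 for c in cols)
        s = int(normal.chroms["chr1"].start.min())
        covered = {c.pos - 1 for c in cols}
        assert covered == set(range(s, s + 100)) | set(range(s + 200, s + 300))

    def test_pileup_roundtrip_matches_columns(self, tmp_path, scenario):
        ref = scenario["reference"]
        normal = scenario["normal"]
        truth = scenario["truth"]
        loci = [(t.chrom, t.pos) for t in truth.snvs[:5]]
        path = tmp_path / "subset.tsv"
        # emit a tiny sample built from one chromosome to keep the file small
        cols = sd.pileup_columns(normal, ref, loci)
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\tfwd_bases\tfwd_quals\trev_bases\trev_quals\n")
            for c in cols:
                fh.write("\t".join([
                    c.chrom, str(c.pos), c.ref,
                    "".join(b for b, _ in c.fwd) or "*",
                    "".join(chr(q + 33) for _, q in c.fwd) or "*",
                    "".join(b for b, _ in c.rev) or "*",
                    "".join(chr(q + 33) for _, q in c.rev) or "*"]) + "\n")
        back = sd.read_pileup_tsv(str(path))
        assert [(c.chrom, c.pos, c.ref, c.fwd, c.rev) for c in back] == \
               [(c.chrom, c.pos, c.ref, c.fwd, c.rev) for c in cols]

    def test_empty_sample_emits_header_only(self, tmp_path):
        cfg = sd.SimulationConfig(chromosomes=[("chr1", 1000)], seed=3,
                                  normal_depth=0.0, tumor_depth=0.0)
        ref = sd.simulate_reference(cfg)
        normal, _, _ = sd.simulate_pair(cfg, ref)
        sam = tmp_path / "empty.sam"
        sd.emit_alignments(normal, str(sam))
        lines = sam.read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)
        pu = tmp_path / "empty.tsv"
        sd.emit_pileups(normal, ref, str(pu))
        assert all(l.startswith("#") for l in pu.read_text().splitlines())

    def test_sam_roundtrip_preserves_records(self, tmp_path):
        cfg = sd.SimulationConfig(
            chromosomes=[("chr1", 20_000), ("chr2", 20_000)], seed=29,
            normal_depth=5, tumor_depth=5,
            indels=[sd.IndelSpike("chr1", 10_000, "del", 3, origin="germline")],
            translocations=[sd.TxSpike("chr1", 15_000, "chr2", 5_000,
                                       origin="germline")])
        ref = sd.simulate_reference(cfg)
        normal, _, _ = sd.simulate_pair(cfg, ref)
        path = tmp_path / "normal.sam"
        sd.emit_alignments(normal, str(path))
        table = read_table_from_sam(str(path))
        expect = normal.to_read_table()
        assert len(table) == len(expect)
        # SAM is coordinate sorted per chromosome, as is the table
        assert np.array_equal(table.start, expect.start)
        assert np.array_equal(table.insert, expect.insert)
        assert np.array_equal(table.mate_chrom_ids, expect.mate_chrom_ids)
        got_ops = sorted((table.chrom_names[table.chrom_ids[r]], o.start, o.kind,
                          o.length) for r, ops in table.indel_ops.items()
                         for o in ops)
        want_ops = sorted((expect.chrom_names[expect.chrom_ids[r]], o.start,
                           o.kind, o.length)
                          for r, ops in expect.indel_ops.items() for o in ops)
        assert got_ops == want_ops

    def test_unsorted_sample_rejected(self):
        cfg = base_config(normal_depth=1)
        ref = sd.simulate_reference(cfg)
        normal, _, _ = sd.simulate_pair(cfg, ref)
        cr = normal.chroms["chr1"]
        cr.start[:2] = cr.start[:2][::-1] if cr.start[0] < cr.start[1] else cr.start[:2]
        cr.start[0], cr.start[1] = cr.start[1] + 100, cr.start[0]
        with pytest.raises(ValueError, match="sorted"):
            sd.emit_alignments(normal, "/dev/null")


class TestTruthWriting:
    def make_truth(self, n_snv=100, n_indel=20, n_tx=2):
        t = sd.TruthSet()
        for i in range(n_snv):
            t.snvs.append(sd.TruthSnv("chr1", 1000 + i * 10, "A", "G", 0.5,
                                      "somatic"))
        for i in range(n_indel):
            t.indels.append(sd.TruthIndel("chr1", 5000 + i * 50, 5003 + i * 50,
                                          "del", "ACG", 0.5, "somatic"))
        for i in range(n_tx):
            t.translocations.append(sd.TruthTx("chr1", 100, "chr2", 200,
                                               "somatic"))
        return t

    def test_record_counts_conserved(self, tmp_path):
        paths = sd.write_truth(self.make_truth(), str(tmp_path))
        vcf_records = [l for l in open(paths["vcf"]) if not l.startswith("#")]
        assert len(vcf_records) == 120
        assert len(open(paths["bedpe"]).readlines()) == 2

    def test_empty_truth_headers_only(self, tmp_path):
        paths = sd.write_truth(sd.TruthSet(), str(tmp_path))
        assert all(l.startswith("#") for l in open(paths["vcf"]))
        assert open(paths["bed"]).read() == ""
        assert open(paths["bedpe"]).read() == ""

    def test_duplicate_snv_locus_rejected(self):
        t = sd.TruthSet(snvs=[sd.TruthSnv("chr1", 5, "A", "G", 0.5, "somatic"),
                              sd.TruthSnv("chr1", 5, "A", "C", 0.5, "somatic")])
        with pytest.raises(ValueError):
            t.validate()
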