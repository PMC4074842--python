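"""Unit and property tests for the KS-style pileup genotyper."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaticscan import snvcall as sc
from somaticscan.snvcall import (BaseDistribution, PileupColumn, SnvParams,
                                 call_genotype, expected_base_distribution,
                                 is_high_quality_homref, ks_distance,
                                 locus_error_rate, trim_zero_quality,
                                 tumor_variant_consensus)


def reads(pattern):
    """'A:30x5,G:20x2' -> [('A',30)]*5 + [('G',20)]*2"""
    out = []
    for part in pattern.split(","):
        if not part:
            continue
        bq, _, n = part.partition("x")
        b, q = bq.split(":")
        out.extend([(b, int(q))] * (int(n) if n else 1))
    return out


def col(ref="A", fwd="", rev="", chrom="chr1", pos=100):
    return PileupColumn(chrom, pos, ref, reads(fwd), reads(rev))


# ---------------------------------------------------------------------------
# oracle: brute-force cumulative-difference KS distance
# ---------------------------------------------------------------------------

def ks_oracle(p, q):
    best = 0.0
    cp = cq = 0.0
    for i in range(4):
        cp += p[i]
        cq += q[i]
        best = max(best, abs(cp - cq))
    return best


class TestKsDistance:
    def test_half_gap_het_vs_homref(self):
        p = BaseDistribution((0.5, 0.0, 0.5, 0.0))
        q = BaseDistribution((1.0, 0.0, 0.0, 0.0))
        assert ks_distance(p, q) == pytest.approx(0.5)

    def test_identity_is_zero(self):
        p = BaseDistribution((0.3, 0.2, 0.4, 0.1))
        assert ks_distance(p, p) == 0.0

    def test_matches_enumeration_oracle(self):
        p = (0.8, 0.0, 0.2, 0.0)
        q = (0.99, 0.003333, 0.003333, 0.003334)
        d = ks_distance(BaseDistribution(p), BaseDistribution(q))
        assert d == pytest.approx(ks_oracle(p, q))
        assert d == pytest.approx(0.1933, abs=5e-4)

    def test_rejects_non_normalized(self):
        with pytest.raises(ValueError):
            BaseDistribution((0.5, 0.5, 0.5, 0.5))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).filter(lambda v: sum(v) > 0),
           st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).filter(lambda v: sum(v) > 0))
    def test_oracle_equivalence_and_symmetry(self, a, b):
        p = tuple(np.asarray(a) / sum(a))
        q = tuple(np.asarray(b) / sum(b))
        dp, dq = BaseDistribution(p), BaseDistribution(q)
        d = ks_distance(dp, dq)
        assert d == pytest.approx(ks_oracle(p, q), abs=1e-12)
        assert d == pytest.approx(ks_distance(dq, dp))
        assert 0.0 <= d <= 1.0


class TestElementaryOps:
    def test_trim_drops_exactly_zero_quality(self):
        c = PileupColumn("chr1", 10, "A", [("A", 30), ("A", 0), ("G", 20)], [("A", 1)])
        t = trim_zero_quality(c)
        assert t.fwd == [("A", 30), ("G", 20)] and t.rev == [("A", 1)]
        assert len(c.fwd) == 3  # input untouched

    def test_trim_identity_and_empty(self):
        c = col(fwd="A:30x4", rev="A:30x4")
        t = trim_zero_quality(c)
        assert t.fwd == c.fwd and t.rev == c.rev
        z = PileupColumn("chr1", 1, "A", [("A", 0)], [("C", 0)])
        assert trim_zero_quality(z).depth == 0

    @pytest.mark.parametrize("quals,expected", [
        ([30, 30, 30], 0.001),
        ([10, 20], 0.055),
    ])
    def test_locus_error_rate(self, quals, expected):
        strand = [("A", q) for q in quals]
        assert locus_error_rate(strand) == pytest.approx(expected)

    def test_locus_error_rate_empty_strand(self):
        with pytest.raises(ValueError):
            locus_error_rate([])

    @pytest.mark.parametrize("gt,e,expected", [
        (("A", "A"), 0.0, (1.0, 0.0, 0.0, 0.0)),
        (("A", "G"), 0.0, (0.5, 0.0, 0.5, 0.0)),
        (("A", "A"), 0.03, (0.97, 0.01, 0.01, 0.01)),
    ])
    def test_expected_base_distribution(self, gt, e, expected):
        d = expected_base_distribution(gt, e)
        assert d.p == pytest.approx(expected)
        assert sum(d.p) == pytest.approx(1.0)

    def test_expected_distribution_rejects_bad_allele(self):
        with pytest.raises(ValueError):
            expected_base_distribution(("A", "N"), 0.01)


# ---------------------------------------------------------------------------
# genotype calling against an exhaustive independent oracle
# ---------------------------------------------------------------------------

def genotype_oracle(column, params):
    """Independent re-derivation: enumerate all 10 genotypes, score each
    strand with its empirical cumulative distribution and mean error rate,
    combine via max over strands, break ties by (non-ref count, lexicographic)."""
    order = "ACGT"
    gts = list(itertools.combinations_with_replacement(order, 2))

    def strand_scores(strand):
        counts = {b: 0 for b in order}
        for b, _ in strand:
            counts[b] += 1
        n = len(strand)
        emp = [counts[b] / n for b in order]
        e = sum(10 ** (-q / 10) for _, q in strand) / n
        scores = {}
        for gt in gts:
            exp = [sum(0.5 * ((1 - e) if b == a else e / 3) for a in gt)
                   for b in order]
            scores[gt] = ks_oracle(emp, exp)
        return scores

    per_strand = {}
    for name, strand in (("forward", column.fwd), ("reverse", column.rev)):
        if len(strand) >= max(1, params.min_depth_strand):
            per_strand[name] = strand_scores(strand)
    if not per_strand:
        return None
    combined = {gt: max(s[gt] for s in per_strand.values()) for gt in gts}
    best = min(combined.values())
    tied = [gt for gt, d in combined.items() if abs(d - best) < 1e-12]
    tied.sort(key=lambda gt: (sum(1 for a in gt if a != column.ref), gt))
    return tied[0], best


@pytest.mark.parametrize("fwd,rev,ref,expect_gt", [
    ("A:30x10", "A:30x10", "A", ("A", "A")),
    ("A:30x6,G:30x6", "A:30x6,G:30x6", "A", ("A", "G")),
    ("C:30x12", "C:30x12", "A", ("C", "C")),
    ("A:30x18,G:30x2", "A:30x18,G:30x2", "A", ("A", "A")),
])
def test_call_genotype_matches_oracle(fwd, rev, ref, expect_gt):
    c = col(ref=ref, fwd=fwd, rev=rev)
    params = SnvParams.lenient()
    call = call_genotype(c, params)
    gt, dist = genotype_oracle(c, params)
    assert call.genotype == gt == expect_gt
    assert call.combined_distance == pytest.approx(dist)
    assert call.status == "callable"


def test_error_free_exact_match_has_zero_distance():
    c = col(ref="A", fwd="A:60x5,G:60x5", rev="A:60x5,G:60x5")
    call = call_genotype(c, SnvParams.lenient())
    assert call.genotype == ("A", "G")
    # Q60 error is 1e-6; distance is bounded by the tiny error spread
    assert call.combined_distance < 1e-5


def test_single_strand_variant_is_not_called():
    """A variant seen on only one strand must not yield a variant genotype."""
    c = col(ref="A", fwd="G:30x12", rev="A:30x12")
    call = call_genotype(c, SnvParams.lenient())
    assert call.status == "ambiguous"


def test_untrimmed_column_is_rejected():
    c = PileupColumn("chr1", 5, "A", [("A", 0)], [("A", 30)])
    with pytest.raises(ValueError):
        call_genotype(c, SnvParams.lenient())


def test_low_depth_status():
    c = col(ref="A", fwd="A:30x1", rev="A:30x1")
    assert call_genotype(c, SnvParams.strict()).status == "low_depth"


def test_variant_call_monotone_in_alt_support():
    """Adding alt reads on both strands never reverts a variant call to
    hom-ref while depth gates stay satisfied."""
    params = SnvParams.lenient()
    seen_variant = False
    for k in range(0, 16):
        fwd = f"A:30x10,G:30x{k}" if k else "A:30x10"
        c = col(ref="A", fwd=fwd, rev=fwd)
        call = call_genotype(c, params)
        has_g = "G" in call.genotype and call.status == "callable"
        if seen_variant:
            assert has_g, f"variant lost again at k={k}"
        seen_variant = seen_variant or has_g
    assert seen_variant


class TestHighQualityHomref:
    params = SnvParams.lenient()

    def _hq(self, c):
        t = trim_zero_quality(c)
        return is_high_quality_homref(call_genotype(t, self.params), t, self.params)

    def test_clean_homref_true(self):
        assert self._hq(col(ref="A", fwd="A:30x10", rev="A:30x10"))

    def test_depth_gate(self):
        assert not self._hq(col(ref="A", fwd="A:30x2", rev="A:30x2"))

    def test_alt_fraction_gate(self):
        assert not self._hq(col(ref="A", fwd="A:30x10,G:30x2", rev="A:30x10,G:30x1"))


class TestVariantConsensus:
    def test_fires_at_default_thresholds(self):
        c = col(ref="A", fwd="A:30x17,G:30x3", rev="A:30x17,G:30x3")
        assert tumor_variant_consensus(c, SnvParams.lenient()) == ("G", 3, 3)

    def test_requires_both_strands(self):
        c = col(ref="A", fwd="A:30x15,G:30x5", rev="A:30x20")
        assert tumor_variant_consensus(c, SnvParams.lenient()) is None

    def test_all_reference_returns_none(self):
        c = col(ref="A", fwd="A:30x20", rev="A:30x20")
        assert tumor_variant_consensus(c, SnvParams.lenient()) is None

    def test_pooled_fraction_gate(self):
        c = col(ref="A", fwd="A:30x48,G:30x2", rev="A:30x48,G:30x2")
        # fraction 4/100 < 0.05 lenient floor
        assert tumor_variant_consensus(c, SnvParams.lenient()) is None


def test_strict_profile_no_looser_than_lenient():
    s, l = SnvParams.strict(), SnvParams.lenient()
    assert s.min_depth_total >= l.min_depth_total
    assert s.min_depth_strand >= l.min_depth_strand
    assert s.d_max <= l.d_max
    assert s.consensus_min_alt_per_strand >= l.consensus_min_alt_per_strand
    assert s.consensus_min_alt_fraction >= l.consensus_min_alt_fraction


class TestSomaticWorkflow:
    def test_somatic_call_and_germline_exclusion(self):
        normal = [col(ref="A", fwd="A:30x20", rev="A:30x20", pos=100),
                  col(ref="A", fwd="A:30x10,G:30x10", rev="A:30x10,G:30x10", pos=200)]
        tumor = [col(ref="A", fwd="A:30x12,G:30x8", rev="A:30x12,G:30x8", pos=100),
                 col(ref="A", fwd="A:30x10,G:30x10", rev="A:30x10,G:30x10", pos=200)]
        calls = sc.call_somatic_snvs(normal, tumor, profile="lenient")
        assert [(c.pos, c.alt) for c in calls] == [(100, "G")]

    def test_low_depth_normal_blocks_call(self):
        normal = [col(ref="A", fwd="A:30x2", rev="A:30x1", pos=100)]
        tumor = [col(ref="A", fwd="A:30x12,G:30x8", rev="A:30x12,G:30x8", pos=100)]
        assert sc.call_somatic_snvs(normal, tumor, profile="lenient") == []

    def test_both_profiles_record_provenance(self):
        normal = [col(ref="A", fwd="A:30x20", rev="A:30x20", pos=100),
                  col(ref="A", fwd="A:30x20", rev="A:30x20", pos=200)]
        # pos 100: strong alt (passes strict), pos 200: weak alt (lenient only)
        tumor = [col(ref="A", fwd="A:30x12,G:30x8", rev="A:30x12,G:30x8", pos=100),
                 col(ref="A", fwd="A:30x28,G:30x2", rev="A:30x28,G:30x2", pos=200)]
        calls = sc.call_somatic_snvs(normal, tumor, profile="both")
        by_pos = {c.pos: c.profile for c in calls}
        assert by_pos == {100: "both", 200: "lenient"}

    def test_strand_rule_no_zero_alt_strand(self, scenario):
        ref = scenario["reference"]
        truth = scenario["truth"]
        loci = [(t.chrom, t.pos) for t in truth.snvs]
        from somaticscan import simdata as sd
        ncols = sd.pileup_columns(scenario["normal"], ref, loci)
        tcols = sd.pileup_columns(scenario["tumor"], ref, loci)
        calls = sc.call_somatic_snvs(ncols, tcols, profile="lenient")
        assert calls, "expected somatic calls at spiked loci"
        for c in calls:
            assert c.tumor_alt_fwd > 0 and c.tumor_alt_rev > 0
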