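"""Per-strand KS-style pileup genotyper and somatic SNV workflow.

The genotyper compares, on each strand separately, the empirical base
distribution of a pileup column against the expected base distribution of
each of the ten unordered diploid genotypes over {A, C, G, T}, using a
Kolmogorov-Smirnov-style statistic: the maximum absolute difference of the
two cumulative distributions over the fixed base order A < C < G < T.  Base
qualities enter in two ways: bases with quality zero are trimmed before any
comparison, and the remaining qualities set the strand's mean miscall
probability ``e = mean(10^(-Q/10))``, which spreads each genotype's expected
mass as ``q(b) = sum_a 0.5 * ((1 - e) if b == a else e / 3)`` over the two
alleles ``a``.

A variant is only accepted when both strands support it: the combined call
minimises the worse (max-over-strands) distance, and a non-reference call is
demoted to ambiguous unless every participating strand's own best genotype
contains the same non-reference allele(s).

The somatic workflow mirrors a matched tumor/normal subtraction: tumor
columns are screened with a sensitive variant-consensus rule (minimum alt
reads per strand plus a pooled alt-fraction floor), and a site is reported
somatic only when the matched normal column yields a high-quality homozygous
reference genotype.  Two parameter profiles, strict and lenient, can be run
side by side with each call's provenance recorded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BASE_ORDER", "GENOTYPES",
    "PileupColumn", "BaseDistribution", "SnvParams", "GenotypeCall",
    "SomaticSnv",
    "trim_zero_quality", "locus_error_rate", "expected_base_distribution",
    "ks_distance", "call_genotype", "is_high_quality_homref",
    "tumor_variant_consensus", "call_somatic_snvs",
    "consensus_candidate_mask",
]

BASE_ORDER = "ACGT"
_IDX = {b: i for i, b in enumerate(BASE_ORDER)}
#: the 10 unordered diploid genotypes in deterministic order
GENOTYPES: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(BASE_ORDER, 2))


@dataclass
class PileupColumn:
    """Per-locus, per-strand base calls with phred qualities."""

    chrom: str
    pos: int  # 1-based
    ref: str
    fwd: list[tuple[str, int]] = field(default_factory=list)
    rev: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref not in BASE_ORDER:
            raise ValueError(f"reference base must be one of {BASE_ORDER}")
        for base, q in itertools.chain(self.fwd, self.rev):
            if base not in BASE_ORDER or q < 0:
                raise ValueError(f"bad pileup entry ({base!r}, {q})")

    @property
    def depth(self) -> int:
        return len(self.fwd) + len(self.rev)


@dataclass(frozen=True)
class BaseDistribution:
    """Probabilities over the ordered alphabet A < C < G < T."""

    p: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, float)
        if arr.shape != (4,) or np.any(arr < -1e-12) or abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"not a distribution over 4 bases: {self.p}")

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "BaseDistribution":
        arr = np.asarray(counts, float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("empty counts")
        return cls(tuple(arr / total))


@dataclass(frozen=True)
class SnvParams:
    """Thresholds for genotype calling and the somatic workflow.

    The strict and lenient profiles bundle the published dual-threshold idea:
    strict is uniformly no looser than lenient.  All numeric defaults are
    this package's own calibration (the thresholds' roles, not their values,
    come from the method description).
    """

    min_depth_total: int = 6
    min_depth_strand: int = 2
    d_max: float = 0.20
    hq_d_max: float = 0.05
    hq_min_depth: int = 8
    hq_max_alt_fraction: float = 0.02
    consensus_min_alt_per_strand: int = 2
    consensus_min_alt_fraction: float = 0.05
    profile: str = "custom"

    def __post_init__(self) -> None:
        if min(self.min_depth_total, self.min_depth_strand, self.hq_min_depth,
               self.consensus_min_alt_per_strand) < 0:
            raise ValueError("depth thresholds must be >= 0")
        for f in (self.d_max, self.hq_d_max, self.hq_max_alt_fraction,
                  self.consensus_min_alt_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fraction thresholds must be in [0, 1]")

    @classmethod
    def strict(cls) -> "SnvParams":
        return cls(min_depth_total=10, min_depth_strand=3, d_max=0.10,
                   consensus_min_alt_per_strand=3,
                   consensus_min_alt_fraction=0.10, profile="strict")

    @classmethod
    def lenient(cls) -> "SnvParams":
        return cls(min_depth_total=6, min_depth_strand=2, d_max=0.20,
                   consensus_min_alt_per_strand=2,
                   consensus_min_alt_fraction=0.05, profile="lenient")


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    ref: str
    genotype: tuple[str, str]
    strand_best: dict[str, tuple[tuple[str, str], float]]
    combined_distance: float
    depth_fwd: int
    depth_rev: int
    status: str  # "callable" | "low_depth" | "ambiguous"

    @property
    def depth(self) -> int:
        return self.depth_fwd + self.depth_rev


@dataclass
class SomaticSnv:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_alt_fwd: int
    tumor_alt_rev: int
    tumor_depth_fwd: int
    tumor_depth_rev: int
    normal_call: GenotypeCall
    profile: str  # "strict" | "lenient" | "both"

    @property
    def tumor_alt_fraction(self) -> float:
        depth = self.tumor_depth_fwd + self.tumor_depth_rev
        return (self.tumor_alt_fwd + self.tumor_alt_rev) / depth if depth else 0.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def trim_zero_quality(column: PileupColumn) -> PileupColumn:
    """Drop quality-zero bases from both strands (input left untouched)."""
    return PileupColumn(
        column.chrom, column.pos, column.ref,
        [(b, q) for b, q in column.fwd if q > 0],
        [(b, q) for b, q in column.rev if q > 0],
    )


def locus_error_rate(strand: Sequence[tuple[str, int]]) -> float:
    """Mean per-base miscall probability 10^(-Q/10) of one strand's bases."""
    if not strand:
        raise ValueError("error rate undefined for an empty strand")
    return float(np.mean([10.0 ** (-q / 10.0) for _, q in strand]))


def expected_base_distribution(genotype: tuple[str, str], e: float) -> BaseDistribution:
    """Expected base distribution of a diploid genotype at error rate ``e``."""
    a1, a2 = genotype
    if a1 not in BASE_ORDER or a2 not in BASE_ORDER:
        raise ValueError(f"invalid genotype {genotype}")
    if not (0.0 <= e < 1.0):
        raise ValueError("error rate must be in [0, 1)")
    p = np.zeros(4)
    for allele in (a1, a2):
        for b in range(4):
            p[b] += 0.5 * ((1.0 - e) if b == _IDX[allele] else e / 3.0)
    return BaseDistribution(tuple(p))


def ks_distance(p: BaseDistribution, q: BaseDistribution) -> float:
    """Max absolute cumulative difference over the fixed order A < C < G < T."""
    cp = np.cumsum(p.p)
    cq = np.cumsum(q.p)
    return float(np.max(np.abs(cp - cq)))


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def _strand_counts(strand: Sequence[tuple[str, int]]) -> np.ndarray:
    counts = np.zeros(4)
    for b, _ in strand:
        counts[_IDX[b]] += 1
    return counts


def _genotype_distances(counts: np.ndarray, e: float) -> np.ndarray:
    """KS distance to each of the 10 genotype expectations (vectorised)."""
    emp = np.cumsum(counts / counts.sum())
    d = np.empty(len(GENOTYPES))
    for g, gt in enumerate(GENOTYPES):
        exp = np.cumsum(expected_base_distribution(gt, e).p)
        d[g] = np.max(np.abs(emp - exp))
    return d


def _rank_key(gt: tuple[str, str], ref: str) -> tuple[int, tuple[str, str]]:
    non_ref = sum(1 for a in gt if a != ref)
    return (non_ref, gt)


def _argmin_genotype(d: np.ndarray, ref: str) -> tuple[tuple[str, str], float]:
    best = float(np.min(d))
    tied = [GENOTYPES[i] for i in np.flatnonzero(np.isclose(d, best, rtol=0, atol=1e-12))]
    tied.sort(key=lambda gt: _rank_key(gt, ref))
    return tied[0], best


def call_genotype(column: PileupColumn, params: SnvParams) -> GenotypeCall:
    """Diploid genotype call for one (already trimmed) pileup column.

    Each strand with depth >= ``min_depth_strand`` scores all ten genotypes
    against its own empirical distribution and mean error rate; the combined
    call minimises the max-over-strands distance.  Ties prefer the genotype
    with fewer non-reference alleles, then lexicographic order.
    """
    for b, q in itertools.chain(column.fwd, column.rev):
        if q == 0:
            raise ValueError("column contains quality-zero bases; trim first")
    strands = {"forward": column.fwd, "reverse": column.rev}
    per_strand_d: dict[str, np.ndarray] = {}
    strand_best: dict[str, tuple[tuple[str, str], float]] = {}
    for name, strand in strands.items():
        if len(strand) >= max(1, params.min_depth_strand):
            e = locus_error_rate(strand)
            d = _genotype_distances(_strand_counts(strand), e)
            per_strand_d[name] = d
            strand_best[name] = _argmin_genotype(d, column.ref)

    depth_f, depth_r = len(column.fwd), len(column.rev)
    if not per_strand_d:
        return GenotypeCall(column.chrom, column.pos, column.ref,
                            (column.ref, column.ref), {}, 1.0,
                            depth_f, depth_r, "low_depth")

    combined = np.max(np.stack(list(per_strand_d.values())), axis=0)
    genotype, distance = _argmin_genotype(combined, column.ref)

    depth_ok = (depth_f + depth_r >= params.min_depth_total
                and depth_f >= params.min_depth_strand
                and depth_r >= params.min_depth_strand)
    if not depth_ok:
        status = "low_depth"
    elif distance > params.d_max:
        status = "ambiguous"
    else:
        status = "callable"
        non_ref = {a for a in genotype if a != column.ref}
        if non_ref:
            for best_gt, _ in strand_best.values():
                if not non_ref.issubset(set(best_gt)):
                    status = "ambiguous"
                    break
    return GenotypeCall(column.chrom, column.pos, column.ref, genotype,
                        strand_best, float(distance), depth_f, depth_r, status)


def is_high_quality_homref(call: GenotypeCall, column: PileupColumn,
                           params: SnvParams) -> bool:
    """High-quality homozygous-reference test for the matched normal."""
    if call.genotype != (call.ref, call.ref) or call.status != "callable":
        return False
    if call.combined_distance > params.hq_d_max:
        return False
    depth = column.depth
    if depth < params.hq_min_depth:
        return False
    alt = sum(1 for b, _ in itertools.chain(column.fwd, column.rev)
              if b != call.ref)
    return alt / depth <= params.hq_max_alt_fraction


def tumor_variant_consensus(
    column: PileupColumn, params: SnvParams
) -> Optional[tuple[str, int, int]]:
    """Sensitive tumor-side variant screen.

    Returns ``(alt, alt_fwd, alt_rev)`` for the most frequent non-reference
    allele iff it is supported by at least ``consensus_min_alt_per_strand``
    reads on *each* strand and by a pooled fraction of at least
    ``consensus_min_alt_fraction``; otherwise None.
    """
    cf = _strand_counts(column.fwd)
    cr = _strand_counts(column.rev)
    pooled = cf + cr
    pooled_nonref = pooled.copy()
    pooled_nonref[_IDX[column.ref]] = 0
    if pooled_nonref.sum() == 0:
        return None
    top = int(np.argmax(pooled_nonref))  # argmax is lexicographic on ties
    alt = BASE_ORDER[top]
    depth = pooled.sum()
    if (cf[top] >= params.consensus_min_alt_per_strand
            and cr[top] >= params.consensus_min_alt_per_strand
            and pooled_nonref[top] / depth >= params.consensus_min_alt_fraction):
        return alt, int(cf[top]), int(cr[top])
    return None


# ---------------------------------------------------------------------------
# somatic workflow
# ---------------------------------------------------------------------------

def _somatic_at_locus(normal_col: PileupColumn, tumor_col: PileupColumn,
                      params: SnvParams) -> Optional[SomaticSnv]:
    tumor = trim_zero_quality(tumor_col)
    hit = tumor_variant_consensus(tumor, params)
    if hit is None:
        return None
    normal = trim_zero_quality(normal_col)
    if normal.depth == 0:
        return None
    call = call_genotype(normal, params)
    if not is_high_quality_homref(call, normal, params):
        return None
    alt, alt_f, alt_r = hit
    return SomaticSnv(tumor_col.chrom, tumor_col.pos, tumor_col.ref, alt,
                      alt_f, alt_r, len(tumor.fwd), len(tumor.rev),
                      call, params.profile)


def call_somatic_snvs(
    normal_pileups: Iterable[PileupColumn],
    tumor_pileups: Iterable[PileupColumn],
    params: SnvParams | None = None,
    profile: str | None = None,
) -> list[SomaticSnv]:
    """Somatic subtraction over matched pileup columns.

    A locus is somatic when the tumor variant-consensus screen fires and the
    matched normal column is a high-quality homozygous-reference call.  With
    ``profile="both"`` the strict and lenient profiles are run side by side
    and merged, recording per-record provenance ("strict", "lenient" or
    "both"); every strict call is by construction also a lenient call, so
    provenance is "both" for strict hits and "lenient" for the rest.
    """
    if profile is None:
        profile = params.profile if params is not None else "lenient"
    normal_by_locus = {(c.chrom, c.pos): c for c in normal_pileups}
    tumor_cols = list(tumor_pileups)

    if profile == "both":
        bundles = [SnvParams.strict(), SnvParams.lenient()]
    elif profile == "strict":
        bundles = [params if params is not None and params.profile == "custom"
                   else SnvParams.strict()]
    elif profile == "lenient":
        bundles = [params if params is not None and params.profile == "custom"
                   else SnvParams.lenient()]
    else:
        if params is None:
            raise ValueError(f"unknown profile {profile!r}")
        bundles = [params]

    merged: dict[tuple[str, int], SomaticSnv] = {}
    for bundle in bundles:
        for tcol in tumor_cols:
            key = (tcol.chrom, tcol.pos)
            ncol = normal_by_locus.get(key)
            if ncol is None:
                continue
            if ncol.ref != tcol.ref:
                raise ValueError(f"reference mismatch at {key}")
            rec = _somatic_at_locus(ncol, tcol, bundle)
            if rec is None:
                continue
            if key in merged:
                prev = merged[key]
                if prev.profile != rec.profile:
                    prev.profile = "both"
            else:
                merged[key] = rec
    out = sorted(merged.values(), key=lambda r: (r.chrom, r.pos))
    return out


# ---------------------------------------------------------------------------
# vectorised candidate screen (whole-genome scans)
# ---------------------------------------------------------------------------

def consensus_candidate_mask(ref_codes: np.ndarray, counts: np.ndarray,
                             params: SnvParams) -> np.ndarray:
    """Vectorised pre-screen for the variant-consensus rule.

    ``counts`` has shape (2, L, 4) holding quality-trimmed per-strand base
    counts.  Returns a boolean mask of loci where the most frequent pooled
    non-reference allele satisfies the per-strand count and pooled fraction
    thresholds — the loci worth a full pileup-column evaluation.
    """
    L = counts.shape[1]
    pooled = counts.sum(axis=0)  # (L, 4)
    pooled_nonref = pooled.copy()
    pooled_nonref[np.arange(L), ref_codes] = 0
    top = pooled_nonref.argmax(axis=1)
    top_count = np.take_along_axis(pooled_nonref, top[:, None], axis=1)[:, 0]
    depth = pooled.sum(axis=1)
    cf = np.take_along_axis(counts[0], top[:, None], axis=1)[:, 0]
    cr = np.take_along_axis(counts[1], top[:, None], axis=1)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top_count / np.maximum(depth, 1), 0.0)
    return ((cf >= params.consensus_min_alt_per_strand)
            & (cr >= params.consensus_min_alt_per_strand)
            & (frac >= params.consensus_min_alt_fraction)
            & (top_count > 0))
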