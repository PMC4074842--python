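"""Two-step somatic indel filter.

Step 1 removes tumor reads whose absolute outer insert size falls outside
the 50-500 bp interval (bounds inclusive), discarding the poorly anchored
fragments that generate artefactual gapped alignments.  Candidate indels are
then collected by exact-match grouping of the remaining reads' gapped
alignment operations — identical (chrom, start, type, length, sequence) —
with a minimum read support.

Step 2 is the somatic test against the matched normal: the region spanning
5 bp upstream of the indel start to 5 bp downstream of its end is examined
in the normal sample, and the candidate is somatic only if *no* normal read
carries any indel operation intersecting that region; candidates whose
normal region is underpowered (fewer than ``min_normal_depth`` overlapping
reads) are reported as ``low_normal_coverage`` and excluded from the somatic
set rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .records import IndelOp, ReadPairRecord, ReadTable

__all__ = [
    "IndelParams", "IndelCandidate",
    "filter_by_insert", "collect_indel_candidates", "normal_region_test",
    "call_somatic_indels",
]


@dataclass(frozen=True)
class IndelParams:
    insert_min: int = 50
    insert_max: int = 500
    flank: int = 5
    min_tumor_support: int = 3
    min_normal_depth: int = 8
    max_normal_indel_reads: int = 0

    def __post_init__(self) -> None:
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        if self.flank < 0 or self.min_tumor_support < 0 or self.min_normal_depth < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class IndelCandidate:
    chrom: str
    start: int  # 0-based reference footprint
    end: int  # half-open; end == start for insertions
    kind: str  # "ins" | "del"
    sequence: str
    tumor_support: int
    normal_depth: int = 0
    normal_indel_reads: int = 0
    status: str = "untested"  # somatic | germline_or_artifact | low_normal_coverage

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("candidate start after end")
        if self.tumor_support < 1:
            raise ValueError("candidate must have read support")


def filter_by_insert(
    records: ReadTable | Iterable[ReadPairRecord], params: IndelParams
) -> ReadTable | list[ReadPairRecord]:
    """Keep reads with ``insert_min <= |insert| <= insert_max`` (inclusive).

    Order preserved; returns the same container kind it was given.
    """
    if isinstance(records, ReadTable):
        size = np.abs(records.insert)
        rows = np.flatnonzero((size >= params.insert_min) & (size <= params.insert_max))
        return records.subset(rows)
    return [r for r in records
            if params.insert_min <= abs(r.insert) <= params.insert_max]


def collect_indel_candidates(
    tumor_records: ReadTable | Iterable[ReadPairRecord], params: IndelParams
) -> list[IndelCandidate]:
    """Group identical gapped operations across tumor reads into candidates."""
    table = ReadTable.coerce(tumor_records)
    support: dict[tuple[str, int, str, int, str], int] = {}
    for row, ops in table.indel_ops.items():
        chrom = table.chrom_names[int(table.chrom_ids[row])]
        for op in ops:
            key = (chrom, op.start, op.kind, op.length, op.sequence)
            support[key] = support.get(key, 0) + 1
    out = []
    for (chrom, start, kind, length, seq), n in sorted(support.items()):
        if n < params.min_tumor_support:
            continue
        end = start + length if kind == "del" else start
        out.append(IndelCandidate(chrom, start, end, kind, seq, n))
    return out


def _region(candidate: IndelCandidate, params: IndelParams) -> tuple[int, int]:
    # half-open: flank bases upstream of start through flank bases past end
    return (max(0, candidate.start - params.flank), candidate.end + params.flank)


def normal_region_test(
    candidate: IndelCandidate,
    normal_records: ReadTable | Iterable[ReadPairRecord],
    params: IndelParams,
) -> str:
    """Classify one candidate against the flanked region of the normal sample.

    somatic              -- no normal indel evidence in the region and enough
                            normal reads overlap it;
    germline_or_artifact -- at least one normal read carries an indel op
                            intersecting the region (beyond the allowance);
    low_normal_coverage  -- region clean but insufficiently covered.
    """
    table = ReadTable.coerce(normal_records)
    lo, hi = _region(candidate, params)
    cid = (table.chrom_names.index(candidate.chrom)
           if candidate.chrom in table.chrom_names else -1)
    on_chrom = table.chrom_ids == cid
    overlap = on_chrom & (table.start < hi) & (table.end > lo)
    depth = int(np.count_nonzero(overlap))
    indel_reads = 0
    for row, ops in table.indel_ops.items():
        if not overlap[row]:
            continue
        for op in ops:
            o_lo, o_hi = op.ref_interval
            if o_lo < hi and o_hi > lo:
                indel_reads += 1
                break
    candidate.normal_depth = depth
    candidate.normal_indel_reads = indel_reads
    if indel_reads > params.max_normal_indel_reads:
        candidate.status = "germline_or_artifact"
    elif depth >= params.min_normal_depth:
        candidate.status = "somatic"
    else:
        candidate.status = "low_normal_coverage"
    return candidate.status


def call_somatic_indels(
    tumor_records: ReadTable | Iterable[ReadPairRecord],
    normal_records: ReadTable | Iterable[ReadPairRecord],
    params: IndelParams | None = None,
) -> list[IndelCandidate]:
    """Two-step pipeline: insert filter -> candidates -> normal region test.

    Returns every candidate with its status set; the somatic subset is the
    records with ``status == "somatic"``.
    """
    params = params or IndelParams()
    tumor = ReadTable.coerce(tumor_records)
    normal = ReadTable.coerce(normal_records)
    if set(tumor.chrom_names).isdisjoint(normal.chrom_names) and len(tumor.chrom_names):
        raise ValueError("tumor and normal share no chromosomes; reference mismatch?")
    filtered = filter_by_insert(tumor, params)
    candidates = collect_indel_candidates(filtered, params)
    for cand in candidates:
        normal_region_test(cand, normal, params)
    return candidates
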