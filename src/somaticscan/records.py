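"""Shared aligned-read containers for the detectors.

The three fragment-level detectors (copy number, indel, translocation) all
consume the same view of an alignment: one row per aligned read carrying its
own span, the signed outer insert (SAM TLEN), mate placement and any gapped
(indel) operations.  Two interchangeable containers are provided:

``ReadPairRecord``
    a plain dataclass, convenient for fixtures and small inputs;
``ReadTable``
    a columnar (numpy) container for whole-genome inputs, constructible from
    a list of records or directly from a SAM file via :func:`read_table_from_sam`.

Every detector accepts either form and normalises through
:meth:`ReadTable.coerce`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "IndelOp",
    "ReadPairRecord",
    "ReadTable",
    "read_table_from_sam",
]


@dataclass(frozen=True)
class IndelOp:
    """One gapped alignment operation, in reference coordinates.

    ``start`` is the 0-based reference position of the first deleted base
    (deletions) or of the base immediately following the insertion point
    (insertions).  ``sequence`` holds the deleted reference bases or the
    inserted read bases.
    """

    start: int
    kind: str  # "ins" | "del"
    length: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"indel kind must be 'ins' or 'del', got {self.kind!r}")
        if self.length <= 0:
            raise ValueError("indel length must be positive")

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Reference footprint, 0-based half-open (point interval for insertions)."""
        if self.kind == "del":
            return (self.start, self.start + self.length)
        return (self.start, self.start + 1)


@dataclass
class ReadPairRecord:
    """One aligned read of a paired-end fragment (mirrors one SAM line)."""

    chrom: str
    start: int  # 0-based leftmost aligned position
    end: int  # exclusive end of the aligned reference span
    strand: str  # "+" or "-"
    insert: int  # signed outer insert (SAM TLEN); >0 on the leftmost mate
    mate_chrom: str | None
    mate_pos: int
    proper_pair: bool = True
    mate_mapped: bool = True
    indels: tuple[IndelOp, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("read end precedes start")


class ReadTable:
    """Columnar set of aligned reads grouped by chromosome.

    Chromosome identity is stored as an index into ``chrom_names`` so that the
    reference header order (used for deterministic tie-breaks) travels with
    the data.  ``indel_ops`` is a sparse mapping row -> tuple of IndelOp.
    """

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_ids: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        insert: np.ndarray,
        is_reverse: np.ndarray,
        mate_chrom_ids: np.ndarray,
        mate_pos: np.ndarray,
        proper: np.ndarray,
        indel_ops: dict[int, tuple[IndelOp, ...]] | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ) -> None:
        self.chrom_names = list(chrom_names)
        self.chrom_ids = np.asarray(chrom_ids, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.insert = np.asarray(insert, dtype=np.int64)
        self.is_reverse = np.asarray(is_reverse, dtype=bool)
        self.mate_chrom_ids = np.asarray(mate_chrom_ids, dtype=np.int32)
        self.mate_pos = np.asarray(mate_pos, dtype=np.int64)
        self.proper = np.asarray(proper, dtype=bool)
        self.indel_ops = dict(indel_ops or {})
        self.chrom_lengths = dict(chrom_lengths or {})
        n = len(self.start)
        for arr in (self.chrom_ids, self.end, self.insert, self.is_reverse,
                    self.mate_chrom_ids, self.mate_pos, self.proper):
            if len(arr) != n:
                raise ValueError("ReadTable column lengths differ")

    def __len__(self) -> int:
        return len(self.start)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[ReadPairRecord],
        chrom_names: Sequence[str] | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ) -> "ReadTable":
        records = list(records)
        if chrom_names is None:
            seen: list[str] = []
            for r in records:
                if r.chrom not in seen:
                    seen.append(r.chrom)
                if r.mate_chrom is not None and r.mate_chrom not in seen:
                    seen.append(r.mate_chrom)
            chrom_names = seen
        idx = {c: i for i, c in enumerate(chrom_names)}
        n = len(records)
        chrom_ids = np.empty(n, dtype=np.int32)
        start = np.empty(n, dtype=np.int64)
        end = np.empty(n, dtype=np.int64)
        insert = np.empty(n, dtype=np.int64)
        is_rev = np.empty(n, dtype=bool)
        mate_ids = np.empty(n, dtype=np.int32)
        mate_pos = np.empty(n, dtype=np.int64)
        proper = np.empty(n, dtype=bool)
        ops: dict[int, tuple[IndelOp, ...]] = {}
        for i, r in enumerate(records):
            chrom_ids[i] = idx[r.chrom]
            start[i] = r.start
            end[i] = r.end
            insert[i] = r.insert
            is_rev[i] = r.strand == "-"
            mate_ids[i] = idx[r.mate_chrom] if (r.mate_mapped and r.mate_chrom) else -1
            mate_pos[i] = r.mate_pos
            proper[i] = r.proper_pair
            if r.indels:
                ops[i] = tuple(r.indels)
        return cls(chrom_names, chrom_ids, start, end, insert, is_rev,
                   mate_ids, mate_pos, proper, ops, chrom_lengths)

    @classmethod
    def coerce(cls, records: "ReadTable | Iterable[ReadPairRecord]") -> "ReadTable":
        if isinstance(records, ReadTable):
            return records
        return cls.from_records(records)

    # -- access ----------------------------------------------------------

    def to_records(self) -> list[ReadPairRecord]:
        out = []
        for i in range(len(self)):
            mid = int(self.mate_chrom_ids[i])
            out.append(ReadPairRecord(
                chrom=self.chrom_names[int(self.chrom_ids[i])],
                start=int(self.start[i]),
                end=int(self.end[i]),
                strand="-" if self.is_reverse[i] else "+",
                insert=int(self.insert[i]),
                mate_chrom=self.chrom_names[mid] if mid >= 0 else None,
                mate_pos=int(self.mate_pos[i]),
                proper_pair=bool(self.proper[i]),
                mate_mapped=mid >= 0,
                indels=self.indel_ops.get(i, ()),
            ))
        return out

    def rows_for_chrom(self, chrom: str) -> np.ndarray:
        cid = self.chrom_names.index(chrom)
        return np.flatnonzero(self.chrom_ids == cid)

    def subset(self, rows: np.ndarray) -> "ReadTable":
        rows = np.asarray(rows)
        remap = {int(old): new for new, old in enumerate(rows)}
        ops = {remap[i]: v for i, v in self.indel_ops.items() if i in remap}
        return ReadTable(
            self.chrom_names, self.chrom_ids[rows], self.start[rows],
            self.end[rows], self.insert[rows], self.is_reverse[rows],
            self.mate_chrom_ids[rows], self.mate_pos[rows], self.proper[rows],
            ops, self.chrom_lengths)


def _ops_from_cigar(aln: pysam.AlignedSegment) -> tuple[IndelOp, ...]:
    ops: list[IndelOp] = []
    if not aln.cigartuples:
        return ()
    ref = aln.reference_start
    qpos = 0
    seq = aln.query_sequence or ""
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            ref += length
            qpos += length
        elif op == 1:  # I
            ops.append(IndelOp(ref, "ins", length, seq[qpos:qpos + length]))
            qpos += length
        elif op == 2:  # D
            ops.append(IndelOp(ref, "del", length))
            ref += length
        elif op in (4,):  # S
            qpos += length
        elif op == 3:  # N
            ref += length
    return tuple(ops)


def read_table_from_sam(path: str) -> ReadTable:
    """Load primary aligned reads from a SAM/BAM file into a ReadTable."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        chrom_names = list(fh.references)
        chrom_lengths = dict(zip(fh.references, fh.lengths))
        cid = {c: i for i, c in enumerate(chrom_names)}
        cols: dict[str, list] = {k: [] for k in
                                 ("chrom", "start", "end", "insert", "rev",
                                  "mate", "mpos", "proper")}
        ops: dict[int, tuple[IndelOp, ...]] = {}
        row = 0
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cols["chrom"].append(cid[aln.reference_name])
            cols["start"].append(aln.reference_start)
            cols["end"].append(aln.reference_end or aln.reference_start)
            cols["insert"].append(aln.template_length)
            cols["rev"].append(aln.is_reverse)
            mate_mapped = aln.is_paired and not aln.mate_is_unmapped
            cols["mate"].append(cid[aln.next_reference_name] if mate_mapped else -1)
            cols["mpos"].append(aln.next_reference_start if mate_mapped else -1)
            cols["proper"].append(aln.is_proper_pair)
            o = _ops_from_cigar(aln)
            if o:
                ops[row] = o
            row += 1
    return ReadTable(
        chrom_names,
        np.array(cols["chrom"], dtype=np.int32),
        np.array(cols["start"], dtype=np.int64),
        np.array(cols["end"], dtype=np.int64),
        np.array(cols["insert"], dtype=np.int64),
        np.array(cols["rev"], dtype=bool),
        np.array(cols["mate"], dtype=np.int32),
        np.array(cols["mpos"], dtype=np.int64),
        np.array(cols["proper"], dtype=bool),
        ops,
        chrom_lengths,
    )
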