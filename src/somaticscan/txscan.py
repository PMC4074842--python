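"""Discordant-read-pair interchromosomal translocation detector.

The genome is tiled with non-overlapping 2 kb windows.  In each window the
detector counts all aligned reads, the discordant reads (mate mapped to a
different chromosome), and a histogram of the mates' chromosomes; the
"highest hit" is the modal mate chromosome and the *hit discordant reads*
are the discordant reads pointing at it.  The test statistic per window is
the proportion of hit discordant reads among all aligned reads in the
window.

Under the null (chimeric library noise) these proportions are treated as
draws from a common distribution per chromosome; a window is an outlier
when its proportion exceeds ``mean + 3*SD`` of its chromosome's proportions
and carries at least ``min_hit_reads`` hit reads (the support floor replaces
the visual inspection step with an explicit gate plus an emitted z-score).
The breakpoint regions of a call are the spans of the hit reads' positions
in the window and of their mates' positions on the partner chromosome;
adjacent flagged windows pointing at the same partner are merged.

Somatic calls are obtained by calling tumor and normal separately and
removing any tumor call whose (padded) breakpoint regions overlap a normal
call on the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import ReadPairRecord, ReadTable

logger = logging.getLogger(__name__)

__all__ = [
    "TxParams", "DiscordantWindow", "TranslocationCall",
    "scan_windows", "outlier_cutoff", "detect_translocations",
    "subtract_normal", "scan_translocations",
]


@dataclass(frozen=True)
class TxParams:
    window: int = 2000
    sd_multiplier: float = 3.0
    min_hit_reads: int = 5
    somatic_overlap_padding: int = 1000
    stats_scope: str = "per_chromosome"  # or "genome_wide"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.sd_multiplier <= 0 or self.somatic_overlap_padding < 0:
            raise ValueError("invalid translocation parameters")
        if self.stats_scope not in ("per_chromosome", "genome_wide"):
            raise ValueError("stats_scope must be per_chromosome or genome_wide")


@dataclass
class DiscordantWindow:
    chrom: str
    start: int
    end: int
    total_reads: int
    discordant_reads: int
    mate_histogram: dict[str, int]
    highest_hit: str | None
    hit_count: int
    hit_read_starts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    hit_mate_positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def proportion(self) -> float:
        return self.hit_count / self.total_reads if self.total_reads else 0.0


@dataclass
class TranslocationCall:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    support: int
    proportion: float
    z_score: float
    somatic: bool = False

    def region_a(self) -> tuple[str, int, int]:
        return (self.chrom_a, self.start_a, self.end_a)

    def region_b(self) -> tuple[str, int, int]:
        return (self.chrom_b, self.start_b, self.end_b)


# ---------------------------------------------------------------------------

def scan_windows(
    records: ReadTable | Iterable[ReadPairRecord], params: TxParams | None = None
) -> list[DiscordantWindow]:
    """Per-window discordant-read accounting (non-overlapping windows).

    Windows with zero aligned reads are omitted.  The highest hit is the
    modal mate chromosome; ties break to the chromosome earliest in
    reference (header) order.
    """
    params = params or TxParams()
    table = ReadTable.coerce(records)
    out: list[DiscordantWindow] = []
    n_chroms = len(table.chrom_names)
    for cid, chrom in enumerate(table.chrom_names):
        rows = np.flatnonzero(table.chrom_ids == cid)
        if len(rows) == 0:
            continue
        starts = table.start[rows]
        widx = (starts // params.window).astype(np.int64)
        n_win = int(widx.max()) + 1
        totals = np.bincount(widx, minlength=n_win)
        disc = (table.mate_chrom_ids[rows] >= 0) & (table.mate_chrom_ids[rows] != cid)
        # histogram per (window, mate chromosome)
        flat = widx[disc] * n_chroms + table.mate_chrom_ids[rows][disc]
        hist = np.bincount(flat, minlength=n_win * n_chroms).reshape(n_win, n_chroms)
        disc_per_win = hist.sum(axis=1)
        for w in np.flatnonzero(totals > 0):
            mate_hist = {table.chrom_names[m]: int(hist[w, m])
                         for m in np.flatnonzero(hist[w] > 0)}
            if mate_hist:
                best = int(np.argmax(hist[w]))  # argmax ties -> earliest in header
                hit_count = int(hist[w, best])
                in_win = rows[(widx == w) & disc
                              & (table.mate_chrom_ids[rows] == best)]
                hit_starts = table.start[in_win]
                hit_mates = table.mate_pos[in_win]
                highest = table.chrom_names[best]
            else:
                highest, hit_count = None, 0
                hit_starts = np.empty(0, np.int64)
                hit_mates = np.empty(0, np.int64)
            out.append(DiscordantWindow(
                chrom=chrom, start=int(w) * params.window,
                end=(int(w) + 1) * params.window,
                total_reads=int(totals[w]),
                discordant_reads=int(disc_per_win[w]),
                mate_histogram=mate_hist, highest_hit=highest,
                hit_count=hit_count, hit_read_starts=hit_starts,
                hit_mate_positions=hit_mates))
    return out


def outlier_cutoff(
    windows: Sequence[DiscordantWindow], params: TxParams | None = None
) -> dict[str, tuple[float, float, float]]:
    """Per-scope (mean, sd, cutoff = mean + sd_multiplier * sample SD).

    Scopes with fewer than two windows yield no entry (and hence no calls).
    With SD = 0 the cutoff equals the mean and only windows strictly above
    it can be flagged, so uniform scopes produce nothing.
    """
    params = params or TxParams()
    groups: dict[str, list[float]] = {}
    for w in windows:
        scope = w.chrom if params.stats_scope == "per_chromosome" else "genome"
        groups.setdefault(scope, []).append(w.proportion)
    out = {}
    for scope, props in groups.items():
        if len(props) < 2:
            logger.info("scope %s has <2 windows; no translocation calls", scope)
            continue
        arr = np.asarray(props)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        out[scope] = (mean, sd, mean + params.sd_multiplier * sd)
    return out


def detect_translocations(
    windows: Sequence[DiscordantWindow],
    cutoffs: dict[str, tuple[float, float, float]],
    params: TxParams | None = None,
) -> list[TranslocationCall]:
    """Flag outlier windows and refine breakpoint regions from read spans.

    Adjacent flagged windows on the same chromosome sharing the same highest
    hit merge into one call.  Breakpoint regions are ``[min, max+1)`` of the
    hit reads' positions and of their mates' positions.
    """
    params = params or TxParams()
    flagged: list[tuple[DiscordantWindow, float]] = []
    for w in windows:
        scope = w.chrom if params.stats_scope == "per_chromosome" else "genome"
        if scope not in cutoffs:
            continue
        mean, sd, cutoff = cutoffs[scope]
        if w.proportion > cutoff and w.hit_count >= params.min_hit_reads:
            z = (w.proportion - mean) / sd if sd > 0 else float("inf")
            flagged.append((w, z))

    calls: list[TranslocationCall] = []
    group: list[tuple[DiscordantWindow, float]] = []

    def flush() -> None:
        if not group:
            return
        ws = [w for w, _ in group]
        starts = np.concatenate([w.hit_read_starts for w in ws])
        mates = np.concatenate([w.hit_mate_positions for w in ws])
        support = sum(w.hit_count for w in ws)
        total = sum(w.total_reads for w in ws)
        calls.append(TranslocationCall(
            chrom_a=ws[0].chrom,
            start_a=int(starts.min()), end_a=int(starts.max()) + 1,
            chrom_b=ws[0].highest_hit,
            start_b=int(mates.min()), end_b=int(mates.max()) + 1,
            support=support,
            proportion=support / total if total else 0.0,
            z_score=float(max(z for _, z in group)),
        ))
        group.clear()

    prev: DiscordantWindow | None = None
    for w, z in flagged:
        if (group and prev is not None and w.chrom == prev.chrom
                and w.start == prev.end and w.highest_hit == prev.highest_hit):
            group.append((w, z))
        else:
            flush()
            group.append((w, z))
        prev = w
    flush()
    return _merge_reciprocal(calls, params)


def _merge_reciprocal(calls: list[TranslocationCall],
                      params: TxParams) -> list[TranslocationCall]:
    """Collapse the two sides of one junction into a single call.

    A junction is seen from both breakpoints: windows on chromosome A whose
    mates cluster on B, and windows on B whose mates cluster on A.  Two
    calls whose regions mutually overlap (padded by one window) are merged,
    keeping the better-supported orientation.
    """
    pad = params.window
    out: list[TranslocationCall] = []
    for c in calls:
        partner = None
        for o in out:
            if (_regions_overlap(c.region_a(), o.region_b(), pad)
                    and _regions_overlap(c.region_b(), o.region_a(), pad)):
                partner = o
                break
        if partner is None:
            out.append(c)
            continue
        lead, other = (partner, c) if partner.support >= c.support else (c, partner)
        merged = TranslocationCall(
            chrom_a=lead.chrom_a,
            start_a=min(lead.start_a, other.start_b),
            end_a=max(lead.end_a, other.end_b),
            chrom_b=lead.chrom_b,
            start_b=min(lead.start_b, other.start_a),
            end_b=max(lead.end_b, other.end_a),
            support=max(lead.support, other.support),
            proportion=max(lead.proportion, other.proportion),
            z_score=max(lead.z_score, other.z_score),
            somatic=lead.somatic,
        )
        out[out.index(partner)] = merged
    return out


def _regions_overlap(a: tuple[str, int, int], b: tuple[str, int, int],
                     pad: int) -> bool:
    return (a[0] == b[0]) and (a[1] - pad < b[2]) and (a[2] + pad > b[1])


def subtract_normal(
    tumor_calls: Sequence[TranslocationCall],
    normal_calls: Sequence[TranslocationCall],
    params: TxParams | None = None,
) -> list[TranslocationCall]:
    """Drop tumor calls overlapping (padded) any normal call region."""
    params = params or TxParams()
    pad = params.somatic_overlap_padding
    out = []
    for t in tumor_calls:
        hit = False
        for n in normal_calls:
            for tr in (t.region_a(), t.region_b()):
                for nr in (n.region_a(), n.region_b()):
                    if _regions_overlap(tr, nr, pad):
                        hit = True
        if not hit:
            t.somatic = True
            out.append(t)
    return out


def scan_translocations(
    tumor_records: ReadTable | Iterable[ReadPairRecord],
    normal_records: ReadTable | Iterable[ReadPairRecord] | None = None,
    params: TxParams | None = None,
) -> tuple[list[TranslocationCall], list[DiscordantWindow]]:
    """Full scan of the tumor, optionally with normal subtraction."""
    params = params or TxParams()
    t_windows = scan_windows(tumor_records, params)
    t_calls = detect_translocations(t_windows, outlier_cutoff(t_windows, params), params)
    if normal_records is not None:
        n_windows = scan_windows(normal_records, params)
        n_calls = detect_translocations(n_windows, outlier_cutoff(n_windows, params),
                                        params)
        t_calls = subtract_normal(t_calls, n_calls, params)
    return t_calls, t_windows
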