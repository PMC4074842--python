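"""Physical-coverage log2-ratio copy-number scanner.

Copy number is inferred from *physical* coverage: for every proper read pair
whose outer insert is positive and no larger than ``mean + 3*sd`` of the
sample's insert-size distribution, every base under the insert span is
incremented by one.  Coverage is then averaged over sliding windows
(2 kb wide, 1 kb step by default), each sample is normalised by its
genome-wide median window coverage, and the per-window statistic is
``log2(tumor_norm / normal_norm)``.

Two guard rules keep the track finite and clean:

* windows whose *germline* normalised coverage exceeds ``2^repeat_mask_log2``
  (log2 > 3 by default) are masked as high-repeat regions (centromere-like
  pileups) and excluded from the ratio output;
* raw window coverages of zero are replaced by ``zero_replacement`` (1 by
  default) before normalisation, so homozygous deletions produce a deep but
  finite negative ratio instead of -inf (around -3 at typical depths, lower
  at high depth).

Maximal runs of consecutive unmasked windows beyond ``|log2| >=
call_threshold_log2`` are merged into gain/loss segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import ReadPairRecord, ReadTable

logger = logging.getLogger(__name__)

__all__ = [
    "InsertSizeModel", "CnvParams", "CoverageWindow", "CnvSegment",
    "estimate_insert_model", "physical_coverage", "window_coverage",
    "normalize_windows", "log2_ratio_windows", "segment_calls", "scan_cnv",
]


@dataclass(frozen=True)
class InsertSizeModel:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def max_accepted(self) -> float:
        return self.mean + 3.0 * self.sd


@dataclass(frozen=True)
class CnvParams:
    window: int = 2000
    step: int = 1000
    repeat_mask_log2: float = 3.0
    zero_replacement: float = 1.0
    call_threshold_log2: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0 or not (0 < self.step <= self.window):
            raise ValueError("require window > 0 and 0 < step <= window")
        if self.call_threshold_log2 <= 0 or self.zero_replacement <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CoverageWindow:
    chrom: str
    start: int
    end: int
    normal_raw: float
    tumor_raw: float
    normal_norm: float
    tumor_norm: float
    log2_ratio: float | None  # None on masked windows
    masked: bool


@dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    direction: str  # "gain" | "loss"
    window_count: int


# ---------------------------------------------------------------------------

def estimate_insert_model(records: ReadTable | Iterable[ReadPairRecord]) -> InsertSizeModel:
    """Sample mean/SD of proper-pair outer insert sizes (leftmost mates)."""
    table = ReadTable.coerce(records)
    use = table.proper & (table.insert > 0) & (table.mate_chrom_ids == table.chrom_ids)
    inserts = table.insert[use]
    if len(inserts) < 2:
        raise ValueError("need at least 2 proper pairs to estimate insert model")
    return InsertSizeModel(float(np.mean(inserts)), float(np.std(inserts, ddof=1)))


def physical_coverage(
    records: ReadTable | Iterable[ReadPairRecord],
    model: InsertSizeModel,
    chrom_lengths: dict[str, int],
) -> dict[str, np.ndarray]:
    """Per-base physical coverage per chromosome.

    Each accepted pair (proper, mate on the same chromosome, outer insert in
    (0, mean + 3*sd]) increments every base of [start, start + insert).
    Spans running past the chromosome end are clipped with a warning.
    """
    table = ReadTable.coerce(records)
    tracks = {c: np.zeros(l, np.int32) for c, l in chrom_lengths.items()}
    use = (table.proper & (table.insert > 0)
           & (table.mate_chrom_ids == table.chrom_ids)
           & (table.insert <= model.max_accepted))
    for chrom, length in chrom_lengths.items():
        if chrom not in table.chrom_names:
            continue
        cid = table.chrom_names.index(chrom)
        rows = use & (table.chrom_ids == cid)
        starts = table.start[rows]
        ends = starts + table.insert[rows]
        n_clip = int(np.count_nonzero(ends > length))
        if n_clip:
            logger.warning("%d insert spans clipped at end of %s", n_clip, chrom)
            ends = np.minimum(ends, length)
        diff = np.zeros(length + 1, np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        tracks[chrom] = np.cumsum(diff[:-1])
    return tracks


def _window_starts(length: int, params: CnvParams) -> np.ndarray:
    last = length - params.window
    if last < 0:
        return np.empty(0, np.int64)
    return np.arange(0, last + 1, params.step, dtype=np.int64)


def window_coverage(
    track: dict[str, np.ndarray], params: CnvParams
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean per-base physical coverage in sliding windows per chromosome.

    Returns ``{chrom: (window_starts, window_means)}``; trailing partial
    windows are dropped, and chromosomes shorter than one window yield no
    windows (logged).
    """
    out = {}
    for chrom, cov in track.items():
        starts = _window_starts(len(cov), params)
        if len(starts) == 0:
            logger.info("chromosome %s shorter than one window; skipped", chrom)
            out[chrom] = (starts, np.empty(0, float))
            continue
        csum = np.concatenate([[0.0], np.cumsum(cov, dtype=np.float64)])
        means = (csum[starts + params.window] - csum[starts]) / params.window
        out[chrom] = (starts, means)
    return out


def normalize_windows(values: np.ndarray, params: CnvParams | None = None) -> np.ndarray:
    """Divide window values by the genome-wide median of positive values."""
    values = np.asarray(values, float)
    positive = values[values > 0]
    if len(positive) == 0:
        raise ValueError("cannot normalise an all-zero sample")
    return values / np.median(positive)


def log2_ratio_windows(
    tumor_windows: dict[str, tuple[np.ndarray, np.ndarray]],
    normal_windows: dict[str, tuple[np.ndarray, np.ndarray]],
    params: CnvParams,
) -> list[CoverageWindow]:
    """Tumor/normal log2 ratio per window with repeat masking.

    Raw window coverages of zero are replaced by ``zero_replacement`` before
    normalisation; windows whose normalised germline coverage exceeds
    ``2^repeat_mask_log2`` are marked masked and carry no ratio.
    """
    if set(tumor_windows) != set(normal_windows):
        raise ValueError("window grids differ between samples")
    chroms = list(normal_windows)
    for c in chroms:
        if not np.array_equal(tumor_windows[c][0], normal_windows[c][0]):
            raise ValueError(f"window grid mismatch on {c}")
    t_raw = np.concatenate([tumor_windows[c][1] for c in chroms]) if chroms else np.empty(0)
    n_raw = np.concatenate([normal_windows[c][1] for c in chroms]) if chroms else np.empty(0)
    t_rep = np.where(t_raw > 0, t_raw, params.zero_replacement)
    n_rep = np.where(n_raw > 0, n_raw, params.zero_replacement)
    t_norm = normalize_windows(t_rep)
    n_norm = normalize_windows(n_rep)
    masked = np.log2(n_norm) > params.repeat_mask_log2
    log2r = np.log2(t_norm / n_norm)

    out: list[CoverageWindow] = []
    i = 0
    for c in chroms:
        starts = normal_windows[c][0]
        for s in starts:
            out.append(CoverageWindow(
                chrom=c, start=int(s), end=int(s) + params.window,
                normal_raw=float(n_raw[i]), tumor_raw=float(t_raw[i]),
                normal_norm=float(n_norm[i]), tumor_norm=float(t_norm[i]),
                log2_ratio=None if masked[i] else float(log2r[i]),
                masked=bool(masked[i])))
            i += 1
    return out


def segment_calls(windows: Sequence[CoverageWindow], params: CnvParams) -> list[CnvSegment]:
    """Merge runs of consecutive unmasked windows beyond the call threshold."""
    segments: list[CnvSegment] = []
    run: list[CoverageWindow] = []
    run_dir = ""

    def flush() -> None:
        nonlocal run, run_dir
        if run:
            segments.append(CnvSegment(
                chrom=run[0].chrom, start=run[0].start, end=run[-1].end,
                mean_log2=float(np.mean([w.log2_ratio for w in run])),
                direction=run_dir, window_count=len(run)))
        run, run_dir = [], ""

    prev: CoverageWindow | None = None
    for w in windows:
        direction = ""
        if not w.masked and w.log2_ratio is not None:
            if w.log2_ratio >= params.call_threshold_log2:
                direction = "gain"
            elif w.log2_ratio <= -params.call_threshold_log2:
                direction = "loss"
        contiguous = (prev is not None and w.chrom == prev.chrom
                      and w.start <= prev.end)
        if direction and direction == run_dir and contiguous:
            run.append(w)
        else:
            flush()
            if direction:
                run = [w]
                run_dir = direction
        prev = w
    flush()
    return segments


def scan_cnv(
    normal_records: ReadTable | Iterable[ReadPairRecord],
    tumor_records: ReadTable | Iterable[ReadPairRecord],
    chrom_lengths: dict[str, int],
    params: CnvParams | None = None,
) -> tuple[list[CoverageWindow], list[CnvSegment]]:
    """Full scan: insert models, physical coverage, windows, ratios, segments."""
    params = params or CnvParams()
    normal = ReadTable.coerce(normal_records)
    tumor = ReadTable.coerce(tumor_records)
    n_model = estimate_insert_model(normal)
    t_model = estimate_insert_model(tumor)
    n_track = physical_coverage(normal, n_model, chrom_lengths)
    t_track = physical_coverage(tumor, t_model, chrom_lengths)
    n_win = window_coverage(n_track, params)
    t_win = window_coverage(t_track, params)
    windows = log2_ratio_windows(t_win, n_win, params)
    return windows, segment_calls(windows, params)
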