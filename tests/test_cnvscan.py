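"""Unit tests for the physical-coverage log2-ratio copy-number scanner."""

import numpy as np
import pytest

from somaticscan.cnvscan import (CnvParams, CoverageWindow, InsertSizeModel,
                                 estimate_insert_model, log2_ratio_windows,
                                 normalize_windows, physical_coverage,
                                 segment_calls, window_coverage)
from somaticscan.records import ReadPairRecord


def pair(start, insert, chrom="chr1", proper=True, mate_chrom=None):
    """The leftmost read of a proper pair (insert carried positively)."""
    mate_chrom = mate_chrom or chrom
    return ReadPairRecord(chrom, start, start + 100, "+", insert,
                          mate_chrom, start + insert - 100,
                          proper_pair=proper)


class TestInsertModel:
    def test_degenerate_distribution(self):
        m = estimate_insert_model([pair(0, 300), pair(10, 300)])
        assert (m.mean, m.sd, m.max_accepted) == (300.0, 0.0, 300.0)

    def test_mean_sd_arithmetic_oracle(self):
        m = estimate_insert_model([pair(0, 290), pair(10, 310)])
        # independent arithmetic: mean 300, sample SD sqrt(200)
        assert m.mean == pytest.approx(300.0)
        assert m.sd == pytest.approx(np.sqrt(200.0))
        assert m.max_accepted == pytest.approx(300.0 + 3 * np.sqrt(200.0))

    def test_single_pair_errors(self):
        with pytest.raises(ValueError):
            estimate_insert_model([pair(0, 300)])

    def test_ignores_improper_and_interchromosomal(self):
        recs = [pair(0, 300), pair(5, 300),
                pair(50, 900, proper=False),
                pair(60, 300, mate_chrom="chr2")]
        assert estimate_insert_model(recs).sd == 0.0


class TestPhysicalCoverage:
    lengths = {"chr1": 3000}

    def test_single_fragment_span(self):
        model = InsertSizeModel(300, 10)
        track = physical_coverage([pair(1000, 300)], model, self.lengths)["chr1"]
        assert track[999] == 0 and track[1000] == 1
        assert track[1299] == 1 and track[1300] == 0
        assert track.sum() == 300

    def test_insert_gate_excludes_long_fragments(self):
        model = InsertSizeModel(300, 10)  # max accepted 330
        track = physical_coverage([pair(0, 331)], model, self.lengths)["chr1"]
        assert track.sum() == 0

    def test_additivity_of_overlapping_pairs(self):
        model = InsertSizeModel(300, 10)
        track = physical_coverage([pair(100, 300), pair(100, 300)], model,
                                  self.lengths)["chr1"]
        assert track[150] == 2

    def test_mass_conservation(self):
        model = InsertSizeModel(300, 50)  # accepts up to 450
        recs = [pair(0, 300), pair(500, 420), pair(900, 460), pair(1200, 250)]
        accepted = [300, 420, 250]
        track = physical_coverage(recs, model, self.lengths)["chr1"]
        assert track.sum() == sum(accepted)


class TestWindows:
    params = CnvParams(window=2000, step=1000)

    def test_constant_track(self):
        track = {"chr1": np.full(6000, 10.0)}
        starts, means = window_coverage(track, self.params)["chr1"]
        assert starts.tolist() == [0, 1000, 2000, 3000, 4000]
        assert np.allclose(means, 10.0)

    def test_half_covered_window(self):
        cov = np.zeros(2000)
        cov[:1000] = 10.0
        starts, means = window_coverage({"chr1": cov}, self.params)["chr1"]
        assert means.tolist() == [5.0]

    def test_short_chromosome_yields_no_windows(self):
        starts, means = window_coverage({"chr1": np.zeros(1500)}, self.params)["chr1"]
        assert len(starts) == 0

    @pytest.mark.parametrize("values,expected", [
        ([8, 8, 8, 8], [1, 1, 1, 1]),
        ([4, 8, 8, 16], [0.5, 1, 1, 2]),
    ])
    def test_median_normalization(self, values, expected):
        assert normalize_windows(np.array(values, float)).tolist() == expected

    def test_all_zero_normalization_errors(self):
        with pytest.raises(ValueError):
            normalize_windows(np.zeros(4))


def windows_from(tumor, normal, params):
    grid = np.arange(len(tumor)) * params.step
    return log2_ratio_windows({"chr1": (grid, np.asarray(tumor, float))},
                              {"chr1": (grid, np.asarray(normal, float))},
                              params)


class TestLog2Ratios:
    params = CnvParams()

    def test_identical_tracks_give_zero(self):
        ws = windows_from([8, 8, 8, 8], [8, 8, 8, 8], self.params)
        assert all(w.log2_ratio == 0.0 for w in ws)

    def test_zero_replacement_caps_homozygous_deletion(self):
        ws = windows_from([8, 8, 8, 0], [8, 8, 8, 8], self.params)
        # tumor raw 0 -> 1; equal normalisation factors -> log2(1/8) = -3
        assert ws[-1].log2_ratio == pytest.approx(-3.0)
        assert all(np.isfinite(w.log2_ratio) for w in ws if not w.masked)

    def test_repeat_masking_excludes_high_germline_windows(self):
        normal = [8.0] * 20 + [8.0 * 11]  # last window log2 ~ 3.46 after norm
        tumor = [8.0] * 21
        ws = windows_from(tumor, normal, self.params)
        assert ws[-1].masked and ws[-1].log2_ratio is None
        assert sum(w.masked for w in ws) == 1

    def test_grid_mismatch_errors(self):
        params = self.params
        a = {"chr1": (np.array([0, 1000]), np.array([8.0, 8.0]))}
        b = {"chr1": (np.array([0, 2000]), np.array([8.0, 8.0]))}
        with pytest.raises(ValueError):
            log2_ratio_windows(a, b, params)


def mkwin(start, log2, chrom="chr1", masked=False, window=2000):
    return CoverageWindow(chrom, start, start + window, 8, 8, 1, 1,
                          None if masked else log2, masked)


class TestSegmentation:
    params = CnvParams()

    def test_run_merging(self):
        ws = [mkwin(i * 1000, 1.2) for i in range(5)]
        segs = segment_calls(ws, self.params)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end, seg.direction, seg.window_count) == (0, 6000, "gain", 5)
        assert seg.mean_log2 == pytest.approx(1.2)

    def test_alternating_windows_stay_separate(self):
        ws = []
        for i in range(6):
            ws.append(mkwin(i * 1000, 1.2 if i % 2 == 0 else 0.0))
        segs = segment_calls(ws, self.params)
        assert len(segs) == 3
        assert all(s.window_count == 1 for s in segs)

    def test_no_calls_near_zero(self):
        ws = [mkwin(i * 1000, 0.1 * (-1) ** i) for i in range(10)]
        assert segment_calls(ws, self.params) == []

    def test_loss_direction_and_masked_break(self):
        ws = [mkwin(0, -1.5), mkwin(1000, -1.5), mkwin(2000, 0, masked=True),
              mkwin(3000, -1.5)]
        segs = segment_calls(ws, self.params)
        assert [s.direction for s in segs] == ["loss", "loss"]
        assert [s.window_count for s in segs] == [2, 1]
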