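"""Window counting, background filtering and region merge/split."""
import math

import numpy as np
import pandas as pd
import pytest

import chipdiff as cd
from chipdiff.io import GenomicInterval, ReadRecord
from chipdiff.windows import (
    MARK_PROFILES,
    WindowGrid,
    count_windows,
    filter_windows,
    fragments_frame,
    global_background,
    merge_windows,
)


def brute_force_counts(frags: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    """Quadratic fragment x window overlap oracle."""
    windows = grid.windows_frame()
    out = np.zeros(len(windows), dtype=int)
    for _, f in frags.iterrows():
        for i, w in windows.iterrows():
            if f["chrom"] == w["chrom"] and f["start"] < w["end"] and f["end"] > w["start"]:
                out[i] += 1
    return out


class TestCountWindows:
    def test_zero_reads_all_zero(self, toy_genome):
        grid = WindowGrid(toy_genome, 150)
        mat = count_windows({"a": []}, grid)
        assert mat.counts.sum() == 0
        assert mat.library_sizes[0] == 0

    def test_single_plus_read_hits_two_windows(self, toy_genome):
        grid = WindowGrid(toy_genome, 150)
        reads = [ReadRecord("chr1", 100, 200, "+")]
        mat = count_windows({"a": reads}, grid, fragment_length=147)
        hit = mat.windows[mat.counts[:, 0] > 0]
        # fragment [100, 247) overlaps windows [0,150) and [150,300)
        assert list(hit["start"]) == [0, 150]

    def test_minus_strand_extension_is_directional(self, toy_genome):
        grid = WindowGrid(toy_genome, 150)
        reads = [ReadRecord("chr1", 200, 300, "-")]
        mat = count_windows({"a": reads}, grid, fragment_length=147)
        hit = mat.windows[mat.counts[:, 0] > 0]
        # fragment [153, 300): only window [150,300)
        assert list(hit["start"]) == [150]

    def test_matches_brute_force_oracle(self, toy_genome):
        rng = np.random.default_rng(0)
        grid = WindowGrid(toy_genome, 150)
        reads = [
            ReadRecord(rng.choice(["chr1", "chr2"]), s, s + 100,
                       rng.choice(["+", "-"]))
            for s in rng.integers(0, 40_000, 50)
        ]
        mat = count_windows({"a": reads}, grid)
        frags = fragments_frame(reads, toy_genome)
        np.testing.assert_array_equal(mat.counts[:, 0], brute_force_counts(frags, grid))

    def test_blacklisted_windows_absent(self, toy_genome):
        grid = WindowGrid(toy_genome, 150,
                          excluded=[GenomicInterval("chr1", 0, 450)])
        mat = count_windows({"a": [ReadRecord("chr1", 10, 110, "+")]}, grid)
        assert not ((mat.windows["chrom"] == "chr1") & (mat.windows["start"] < 450)).any()

    def test_extension_clipped_at_chromosome_end(self, toy_genome):
        reads = [ReadRecord("chr2", 49_990, 49_999, "+")]
        frags = fragments_frame(reads, toy_genome, fragment_length=147)
        assert frags["end"].iloc[0] == 50_000


class TestBackground:
    def test_uniform_coverage_background_matches_window_abundance(self, toy_genome):
        # evenly spaced fragments: every bin equal, scaled bin abundance equals
        # the (uniform) window abundance
        reads = [ReadRecord("chr1", s, s + 147, "+", is_fragment=True)
                 for s in range(0, 99_000, 20)]
        grid = WindowGrid(cd.GenomeDeclaration({"chr1": 100_000}), 100, step=100)
        bg = global_background({"a": reads}, grid, bin_width=2000)
        mat = count_windows({"a": reads}, grid)
        interior = mat.abundance()[5:-5]
        assert abs(bg.global_background - np.median(interior)) < 0.1

    def test_two_bin_toy_formula(self):
        genome = cd.GenomeDeclaration({"chr1": 4000})
        grid = WindowGrid(genome, 150)
        reads = [ReadRecord("chr1", 100, 101, "+", is_fragment=True)] * 10 + [
            ReadRecord("chr1", 2100, 2101, "+", is_fragment=True)] * 30
        bg = global_background({"a": reads}, grid, bin_width=2000)
        n = 40
        scale = (2000 + 146) / (150 + 146)
        expected = np.median([
            np.log2((c / scale + 0.5) / (n + 1) * 1e6) for c in (10, 30)
        ])
        assert bg.global_background == pytest.approx(expected, abs=1e-9)

    def test_cpm_scale_invariance(self, toy_genome):
        grid = WindowGrid(toy_genome, 150)
        reads = [ReadRecord("chr1", s, s + 147, "+", is_fragment=True)
                 for s in range(0, 10_000, 10)]
        a1 = count_windows({"a": reads}, grid).abundance()
        a2 = count_windows({"a": reads * 2}, grid).abundance()
        # doubling counts and the library size shifts abundance only through
        # the prior count; at real coverages that shift is negligible
        nz = a1 > a1.min()
        assert np.allclose(a1[nz], a2[nz], atol=0.05)


class TestFilter:
    def _matrix(self, abundances):
        # library size 1e6 - 1 makes abundance = log2(count + 0.5) exactly
        n = len(abundances)
        counts = (2.0 ** np.asarray(abundances) - 0.5).round()
        windows = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 150,
                                "end": np.arange(n) * 150 + 150})
        return cd.WindowCountMatrix(windows, counts[:, None].astype(int),
                                    ["a"], np.array([999_999.0]))

    def test_threshold_is_strict_greater_than(self):
        from chipdiff.windows import BackgroundModel

        mat = self._matrix([8.0, 13.1, 13.0])
        a = mat.abundance()
        # background exactly 5 below window 2: a 5.0 fold change is NOT kept
        bg = BackgroundModel(2000, a[[2]] - 5.0, float(a[2] - 5.0))
        keep = filter_windows(mat, bg, min_log2fc=5.0)
        assert keep.tolist() == [False, True, False]

    def test_uniform_library_nothing_passes(self, toy_genome):
        grid = WindowGrid(toy_genome, 150)
        reads = [ReadRecord("chr1", s, s + 147, "+", is_fragment=True)
                 for s in range(0, 99_000, 200)]
        mat = count_windows({"a": reads}, grid)
        bg = global_background({"a": reads}, grid)
        assert filter_windows(mat, bg, 5.0).sum() == 0


def _frame(pairs, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "start": [p[0] for p in pairs],
                         "end": [p[1] for p in pairs]})


class TestMerge:
    def test_gap_below_max_gap_merges(self):
        regions = merge_windows(_frame([(0, 150), (250, 400)]), max_gap=200,
                                max_width=7000)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 400)

    def test_gap_at_max_gap_does_not_merge(self):
        regions = merge_windows(_frame([(0, 150), (350, 500)]), max_gap=200,
                                max_width=7000)
        assert len(regions) == 2

    def test_single_window_is_itself(self):
        regions = merge_windows(_frame([(300, 450)]), max_gap=200, max_width=7000)
        assert (regions[0].start, regions[0].end) == (300, 450)

    def test_wide_cluster_split_into_bounded_pieces(self):
        starts = list(range(0, 13_700, 150)) + [13_850]  # span exactly 14 000
        windows = _frame([(s, s + 150) for s in starts])
        regions = merge_windows(windows, max_gap=200, max_width=7000)
        assert len(regions) == math.ceil(14_000 / 7000) == 2
        assert all(r.width <= 7000 for r in regions)
        assert regions[0].start == 0 and regions[-1].end == 14_000
        assert sum(len(r.window_indices) for r in regions) == len(windows)

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(3)
        starts = np.cumsum(rng.integers(150, 600, 200))
        windows = _frame([(s, s + 150) for s in starts])
        for profile in MARK_PROFILES.values():
            first = merge_windows(windows, profile.max_gap, profile.max_width)
            again = merge_windows(
                _frame([(r.start, r.end) for r in first]),
                profile.max_gap, profile.max_width,
            )
            assert [(r.start, r.end) for r in first] == [
                (r.start, r.end) for r in again]

    def test_every_region_contains_a_window(self):
        rng = np.random.default_rng(7)
        starts = np.cumsum(rng.integers(150, 400, 300))
        windows = _frame([(s, s + 150) for s in starts])
        regions = merge_windows(windows, 200, 2000)
        assert all(r.window_indices for r in regions)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_windows(_frame([(500, 650), (0, 150)]), 200, 7000)


def test_region_calling_recovers_planted_promoters(default_analysis):
    """>=95% of planted H3K4me3 promoters intersect a called region."""
    ds = default_analysis["dataset"]
    regions = default_analysis["regions"]
    prom = ds.tss.promoters(1000).loc[ds.truth["k4"].to_numpy()]
    rs = np.array([r.start for r in regions])
    re_ = np.array([r.end for r in regions])
    hit = sum(
        bool(((re_ > p.start) & (rs < p.end)).any()) for p in prom.itertuples()
    )
    assert hit / len(prom) >= 0.95


def test_no_region_overlaps_blacklist(toy_genome):
    bl = [GenomicInterval("chr1", 20_000, 30_000)]
    grid = WindowGrid(toy_genome, 150, excluded=bl)
    rng = np.random.default_rng(11)
    reads = [cd.ReadRecord("chr1", int(s), int(s) + 100, "+")
             for s in rng.integers(15_000, 35_000, 3000)]
    mat = count_windows({"a": reads}, grid)
    bg = global_background({"a": reads}, grid)
    keep = filter_windows(mat, bg, 1.0)
    regions = merge_windows(mat.windows.loc[keep].reset_index(drop=True), 200, 7000)
    for r in regions:
        assert r.end <= 20_000 or r.start >= 30_000
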