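"""Genome-grid window counting and enriched-region calling.

The engine mirrors the window-based (csaw-style) strategy: count MAPQ-filtered
fragments in small sliding windows across the genome, estimate a single global
background level from wide contiguous bins, keep windows whose abundance
exceeds background by a mark-specific log2 fold change, then merge nearby kept
windows into regions with a maximum region width.

Mark profiles bundle the published parameter sets:

========== ====== ========= ======= =========
profile    window min_log2fc max_gap max_width
========== ====== ========= ======= =========
h3k4me3      150      5       200     7000
h3k27me3     150      7       400     7000
kdm1a        150      6       100     2000
========== ====== ========= ======= =========
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import GenomeDeclaration, GenomicInterval, ReadRecord, reads_to_frame

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_LENGTH = 147  # mononucleosome


@dataclass(frozen=True)
class MarkProfile:
    name: str
    window_width: int
    min_log2fc: float
    max_gap: int
    max_width: int


MARK_PROFILES: dict[str, MarkProfile] = {
    "h3k4me3": MarkProfile("h3k4me3", 150, 5.0, 200, 7000),
    "h3k27me3": MarkProfile("h3k27me3", 150, 7.0, 400, 7000),
    "kdm1a": MarkProfile("kdm1a", 150, 6.0, 100, 2000),
}


class WindowGrid:
    """Tiling (or overlapping) window grid over a declared genome.

    Window ``i`` on a chromosome covers ``[i*step, i*step + width)`` clipped to
    the chromosome end. Windows overlapping the blacklist are dropped.
    """

    def __init__(
        self,
        genome: GenomeDeclaration,
        window_width: int = 150,
        step: Optional[int] = None,
        excluded: Sequence[GenomicInterval] = (),
    ):
        if window_width <= 0:
            raise ValueError("window_width must be positive")
        step = window_width if step is None else step
        if step <= 0:
            raise ValueError("step must be positive")
        self.genome = genome
        self.window_width = int(window_width)
        self.step = int(step)
        self.excluded = list(excluded)
        self._n_windows = {
            chrom: max(1, math.ceil(length / self.step))
            if length >= 1 else 0
            for chrom, length in genome.items()
        }
        # boolean keep-mask per chromosome (False where blacklisted)
        self._keep = {}
        for chrom, n in self._n_windows.items():
            keep = np.ones(n, dtype=bool)
            self._keep[chrom] = keep
        for iv in self.excluded:
            if iv.chrom not in self._keep:
                continue
            lo, hi = self._overlapping_range(iv.chrom, iv.start, iv.end)
            if hi >= lo:
                self._keep[iv.chrom][lo : hi + 1] = False

    def _overlapping_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Index range [lo, hi] of windows overlapping [start, end)."""
        n = self._n_windows[chrom]
        lo = max(0, (start - self.window_width) // self.step + 1)
        hi = min(n - 1, (end - 1) // self.step)
        return lo, hi

    def n_windows(self, chrom: str) -> int:
        return self._n_windows[chrom]

    def keep_mask(self, chrom: str) -> np.ndarray:
        return self._keep[chrom]

    def windows_frame(self) -> pd.DataFrame:
        """All non-blacklisted windows as a (chrom, start, end) frame."""
        frames = []
        for chrom, n in self._n_windows.items():
            idx = np.nonzero(self._keep[chrom])[0]
            starts = idx * self.step
            ends = np.minimum(starts + self.window_width, self.genome.length(chrom))
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class WindowCountMatrix:
    """Windows x libraries fragment counts with per-library totals."""

    windows: pd.DataFrame  # columns chrom, start, end
    counts: np.ndarray  # (n_windows, n_libraries) ints
    samples: list[str]
    library_sizes: np.ndarray  # total counted fragments per library

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError("counts shape does not match windows x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.library_sizes < 0).any():
            raise ValueError("library_sizes must be non-negative")
        # note: column sums may exceed library_sizes because a fragment
        # increments every window it overlaps (up to 2 under 150 bp tiling)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def log2_cpm(self, prior_count: float = 0.5) -> np.ndarray:
        """Prior-guarded log2 counts-per-million, per window per library."""
        return np.log2(
            (self.counts + prior_count) / (self.library_sizes + 1.0) * 1e6
        )

    def abundance(self, prior_count: float = 0.5) -> np.ndarray:
        """Per-window mean log2-CPM across libraries."""
        return self.log2_cpm(prior_count).mean(axis=1)

    def subset(self, mask: np.ndarray) -> "WindowCountMatrix":
        mask = np.asarray(mask)
        return WindowCountMatrix(
            windows=self.windows.loc[mask].reset_index(drop=True),
            counts=self.counts[mask],
            samples=list(self.samples),
            library_sizes=self.library_sizes.copy(),
        )

    def subset_samples(self, names: Sequence[str]) -> "WindowCountMatrix":
        idx = [self.samples.index(n) for n in names]
        return WindowCountMatrix(
            windows=self.windows.copy(),
            counts=self.counts[:, idx],
            samples=list(names),
            library_sizes=self.library_sizes[idx],
        )


@dataclass
class BackgroundModel:
    """Global non-specific enrichment level from wide contiguous bins."""

    bin_width: int
    bin_abundance: np.ndarray  # per-bin mean log2-CPM rescaled to window width
    global_background: float  # median over bins


@dataclass
class EnrichedRegion:
    """A merged cluster of kept windows (a called region / peak)."""

    chrom: str
    start: int
    end: int
    window_indices: list[int]
    abundance: float = float("nan")

    @property
    def width(self) -> int:
        return self.end - self.start

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               score=None if math.isnan(self.abundance) else self.abundance)


ReadsLike = Union[Iterable[ReadRecord], pd.DataFrame]


def fragments_frame(
    reads: ReadsLike,
    genome: GenomeDeclaration,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> pd.DataFrame:
    """Directionally extend single-end reads to ``fragment_length`` fragments.

    Paired-end records (``is_fragment``) are used as-is. Extensions running
    past a chromosome end are clipped (with a single warning).
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    if not isinstance(reads, pd.DataFrame):
        reads = reads_to_frame(reads)
    if len(reads) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    unknown = set(reads["chrom"]) - set(genome.chromosomes)
    if unknown:
        raise ValueError(f"unknown chromosome {sorted(unknown)[0]!r} in reads")
    start = reads["start"].to_numpy(dtype=np.int64, copy=True)
    end = reads["end"].to_numpy(dtype=np.int64, copy=True)
    single = ~reads["is_fragment"].to_numpy(dtype=bool)
    plus = (reads["strand"] == "+").to_numpy()
    fwd = single & plus
    rev = single & ~plus
    end[fwd] = start[fwd] + fragment_length
    start[rev] = end[rev] - fragment_length
    out = pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "start": start, "end": end})
    clipped = 0
    for chrom, sub in out.groupby("chrom", sort=False):
        length = genome.length(chrom)
        idx = sub.index
        over = (sub["end"] > length) | (sub["start"] < 0)
        clipped += int(over.sum())
        out.loc[idx, "start"] = np.clip(sub["start"], 0, length - 1)
        out.loc[idx, "end"] = np.clip(sub["end"], 1, length)
    if clipped:
        logger.warning("clipped %d fragment(s) extending beyond chromosome ends", clipped)
    return out


def _count_one_chrom(starts, ends, n, width, step):
    """Diff-array overlap counting of fragments against a window grid."""
    counts = np.zeros(n + 1, dtype=np.int64)
    lo = np.maximum(0, (starts - width) // step + 1)
    hi = np.minimum(n - 1, (ends - 1) // step)
    ok = hi >= lo
    np.add.at(counts, lo[ok], 1)
    np.add.at(counts, hi[ok] + 1, -1)
    return np.cumsum(counts)[:-1]


def count_windows(
    read_sets: Mapping[str, ReadsLike],
    grid: WindowGrid,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> WindowCountMatrix:
    """Count fragment-window overlaps for each library on the grid.

    A fragment increments every window it overlaps by >= 1 bp. Library size is
    the total number of counted fragments (genome-wide, before the blacklist
    drops windows), so totals are never smaller than per-window column sums.
    """
    samples = list(read_sets)
    per_chrom: dict[str, np.ndarray] = {
        chrom: np.zeros((grid.n_windows(chrom), len(samples)), dtype=np.int64)
        for chrom in grid.genome.chromosomes
    }
    library_sizes = np.zeros(len(samples), dtype=np.int64)
    for j, name in enumerate(samples):
        frags = fragments_frame(read_sets[name], grid.genome, fragment_length)
        library_sizes[j] = len(frags)
        for chrom, sub in frags.groupby("chrom", sort=False):
            n = grid.n_windows(chrom)
            if n == 0:
                continue
            per_chrom[chrom][:, j] += _count_one_chrom(
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                n, grid.window_width, grid.step,
            )
    windows = grid.windows_frame()
    blocks = [per_chrom[chrom][grid.keep_mask(chrom)] for chrom in grid.genome.chromosomes]
    counts = np.vstack(blocks) if blocks else np.zeros((0, len(samples)), dtype=np.int64)
    return WindowCountMatrix(windows=windows, counts=counts,
                             samples=samples, library_sizes=library_sizes)


def global_background(
    read_sets: Mapping[str, ReadsLike],
    grid: WindowGrid,
    bin_width: int = 2000,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    prior_count: float = 0.5,
) -> BackgroundModel:
    """Estimate the global background level from wide contiguous bins.

    Fragments are counted in ``bin_width`` contiguous bins and rescaled to
    window-equivalent counts before the prior is added: an interval of width
    w collects fragments whose starts span ``w + fragment_length - 1`` bp,
    so bin counts are divided by the ratio of *effective* widths (scaling
    the raw count, not the prior, keeps zero bins and zero windows at the
    same abundance). The global background is the median over bins of the
    mean log2-CPM across libraries.
    """
    if bin_width < grid.window_width:
        raise ValueError("bin_width must be >= window width")
    bin_grid = WindowGrid(grid.genome, window_width=bin_width, step=bin_width,
                          excluded=grid.excluded)
    mat = count_windows(read_sets, bin_grid, fragment_length)
    if mat.n_windows == 0:
        raise ValueError("no background bins: genome shorter than bin width")
    scale = (bin_width + fragment_length - 1) / (
        grid.window_width + fragment_length - 1
    )
    scaled_log2cpm = np.log2(
        (mat.counts / scale + prior_count) / (mat.library_sizes + 1.0) * 1e6
    )
    bin_ab = scaled_log2cpm.mean(axis=1)
    return BackgroundModel(bin_width=bin_width, bin_abundance=bin_ab,
                           global_background=float(np.median(bin_ab)))


def filter_windows(
    matrix: WindowCountMatrix,
    background: BackgroundModel,
    min_log2fc: float,
    prior_count: float = 0.5,
) -> np.ndarray:
    """Keep-mask: window abundance must exceed background by > min_log2fc."""
    if min_log2fc < 0:
        raise ValueError("min_log2fc must be >= 0")
    return (matrix.abundance(prior_count) - background.global_background) > min_log2fc


def merge_windows(
    windows: pd.DataFrame,
    max_gap: int,
    max_width: int,
    abundance: Optional[np.ndarray] = None,
) -> list[EnrichedRegion]:
    """Merge kept windows into regions; split over-wide clusters.

    Windows whose inter-window gap is < ``max_gap`` join one cluster. A
    cluster spanning S > ``max_width`` bp is cut into ceil(S / max_width)
    contiguous slices of near-equal width (each <= max_width); member windows
    are assigned to the slice holding their midpoint. Slices that end up with
    no member window (possible only for extreme parameter choices) are
    dropped so every emitted region contains at least one kept window.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    chroms = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    order_ok = True
    for chrom in pd.unique(chroms):
        s = starts[chroms == chrom]
        if np.any(np.diff(s) < 0):
            order_ok = False
    if not order_ok:
        raise ValueError("windows must be sorted by (chrom, start)")
    regions: list[EnrichedRegion] = []
    for chrom in pd.unique(chroms):
        sel = np.nonzero(chroms == chrom)[0]
        cs, ce = starts[sel], ends[sel]
        gaps = cs[1:] - ce[:-1]
        breaks = np.nonzero(gaps >= max_gap)[0]
        cluster_bounds = np.concatenate([[0], breaks + 1, [len(sel)]])
        for a, b in zip(cluster_bounds[:-1], cluster_bounds[1:]):
            members = sel[a:b]
            span_start, span_end = int(cs[a]), int(ce[b - 1])
            span = span_end - span_start
            k = max(1, math.ceil(span / max_width))
            bounds = [span_start + (j * span) // k for j in range(k)] + [span_end]
            mids = 0.5 * (starts[members] + ends[members])
            piece_of = np.clip(
                np.searchsorted(bounds, mids, side="right") - 1, 0, k - 1
            )
            for j in range(k):
                mem = members[piece_of == j]
                if len(mem) == 0:
                    continue
                ab = float(np.mean(abundance[mem])) if abundance is not None else float("nan")
                regions.append(
                    EnrichedRegion(chrom=str(chrom), start=int(bounds[j]),
                                   end=int(bounds[j + 1]),
                                   window_indices=[int(i) for i in mem], abundance=ab)
                )
    return regions


def call_regions(
    read_sets: Mapping[str, ReadsLike],
    grid: WindowGrid,
    profile: MarkProfile,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    bin_width: int = 2000,
) -> tuple[list[EnrichedRegion], WindowCountMatrix, np.ndarray, BackgroundModel]:
    """One-call region identification: count, background-filter, merge."""
    matrix = count_windows(read_sets, grid, fragment_length)
    background = global_background(read_sets, grid, bin_width, fragment_length)
    keep = filter_windows(matrix, background, profile.min_log2fc)
    kept = matrix.windows.loc[keep].reset_index(drop=True)
    abundance_kept = matrix.abundance()[keep]
    regions = merge_windows(kept, profile.max_gap, profile.max_width, abundance_kept)
    return regions, matrix, keep, background
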