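"""RPKM-normalized fixed-bin coverage tracks for browser inspection."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenomeDeclaration, GenomicInterval, write_bedgraph
from .windows import ReadsLike, _count_one_chrom, fragments_frame


@dataclass
class CoverageTrack:
    """Per-chromosome binned RPKM values for one library."""

    library: str
    bin_width: int
    genome: GenomeDeclaration
    values: dict[str, np.ndarray]  # chrom -> per-bin RPKM
    total_fragments: int

    def bins(self):
        """Yield (GenomicInterval, rpkm) in genome order."""
        for chrom, vals in self.values.items():
            length = self.genome.length(chrom)
            for i, v in enumerate(vals):
                start = i * self.bin_width
                yield GenomicInterval(chrom, start, min(start + self.bin_width, length)), float(v)

    def to_bedgraph(self, path, merge_equal: bool = False) -> None:
        write_bedgraph(list(self.bins()), path, merge_equal=merge_equal,
                       track_name=self.library)


def coverage_rpkm(
    reads: ReadsLike,
    genome: GenomeDeclaration,
    bin_width: int = 10,
    fragment_length: int = 147,
    library: str = "library",
) -> CoverageTrack:
    """Fragment-overlap coverage in fixed bins, RPKM normalized.

    RPKM = count / (bin_width/1000) / (total_fragments/1e6). Raises on an
    empty library (RPKM undefined).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frags = fragments_frame(reads, genome, fragment_length)
    total = len(frags)
    if total == 0:
        raise ValueError("zero fragments: RPKM undefined")
    scale = 1.0 / (bin_width / 1000.0) / (total / 1e6)
    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        n = max(1, -(-length // bin_width))
        sub = frags[frags["chrom"] == chrom]
        counts = _count_one_chrom(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64),
            n, bin_width, bin_width,
        ) if len(sub) else np.zeros(n, dtype=np.int64)
        values[chrom] = counts * scale
    return CoverageTrack(library=library, bin_width=bin_width, genome=genome,
                         values=values, total_fragments=total)
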