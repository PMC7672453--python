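"""Bivalency calls and set-overlap statistics.

Covers the comparisons made between promoter sets: which promoters carry
both H3K4me3 and H3K27me3 (bivalent), whether one promoter set is over- or
under-represented in another (Fisher exact test with explicit universe),
hypergeometric enrichment of gene lists in promoter classes, and the
distance-to-TSS annotation of called regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

from .io import GenomicInterval, TssAnnotation
from .windows import EnrichedRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows in/out of set A, columns in/out of set B."""

    a: int  # in A, in B
    b: int  # in A, not B
    c: int  # not A, in B
    d: int  # not A, not B

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    table: ContingencyTable
    sample_odds_ratio: float  # (a*d)/(b*c)
    odds_ratio: float  # conditional MLE
    p_value: float


def call_bivalent(k4: pd.DataFrame, k27: pd.DataFrame) -> pd.DataFrame:
    """Per-gene bivalency: enriched for both marks at the same promoter.

    Inputs are classified promoter tables (with ``enriched`` columns) for
    each mark, each thresholded with its own cutoff.
    """
    left = k4[["gene_id", "enriched"]].rename(columns={"enriched": "k4_enriched"})
    right = k27[["gene_id", "enriched"]].rename(columns={"enriched": "k27_enriched"})
    out = left.merge(right, on="gene_id", how="outer")
    out[["k4_enriched", "k27_enriched"]] = (
        out[["k4_enriched", "k27_enriched"]].fillna(False).astype(bool)
    )
    out["bivalent"] = out["k4_enriched"] & out["k27_enriched"]
    return out


def fisher_overlap(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> FisherResult:
    """Fisher exact test of overlap between two sets within a universe.

    The universe must be supplied explicitly (it determines the d cell and
    hence the odds ratio); it is echoed to the log for auditability. Returns
    the conditional-MLE odds ratio, the sample odds ratio ad/bc, and the
    exact two-sided p (summing hypergeometric probabilities <= the observed
    table's). A zero margin makes the odds ratio undefined (NaN) with p = 1.
    """
    uni = set(universe)
    sa = set(set_a) & uni
    sb = set(set_b) & uni
    if (set(set_a) - uni) or (set(set_b) - uni):
        raise ValueError("sets must be subsets of the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    table = ContingencyTable(a, b, c, d)
    logger.info("fisher_overlap universe=%d table=[[%d,%d],[%d,%d]]", len(uni), a, b, c, d)
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return FisherResult(table, float("nan"), float("nan"), 1.0)
    sample_or = (a * d) / (b * c) if b * c > 0 else float("inf")
    cond = _conditional_odds_ratio(arr, kind="conditional")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return FisherResult(table, float(sample_or), float(cond.statistic), float(p))


def hypergeom_enrichment(
    hits_in_class: int, class_size: int, set_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric p: P(X >= hits) for overlap of a gene set
    with a promoter class drawn from the universe."""
    if not (0 <= hits_in_class <= min(class_size, set_size) <= universe_size):
        raise ValueError("inconsistent hypergeometric margins")
    return float(stats.hypergeom.sf(hits_in_class - 1, universe_size, set_size, class_size))


def tss_distance_annotation(
    regions: Sequence[EnrichedRegion] | Sequence[GenomicInterval],
    tss: TssAnnotation,
    breaks: Sequence[int] = (1000, 5000, 10000),
) -> tuple[pd.DataFrame, pd.Series]:
    """Nearest-TSS distance per region plus binned proportions.

    Distance is measured from the region midpoint to the closest TSS, and is
    0 when a TSS lies inside the region. Default bins: <1 kb, 1-5 kb,
    5-10 kb, >10 kb; proportions sum to 1. Strand is ignored (positions
    only).
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    labels = (
        [f"<{breaks[0] // 1000} kb"]
        + [f"{a // 1000}-{b // 1000} kb" for a, b in zip(breaks, breaks[1:])]
        + [f">{breaks[-1] // 1000} kb"]
    )
    tss_by_chrom = {
        chrom: np.sort(sub["tss"].to_numpy())
        for chrom, sub in tss.table.groupby("chrom")
    }
    rows = []
    for reg in regions:
        pos = tss_by_chrom.get(reg.chrom)
        if pos is None or len(pos) == 0:
            dist = np.inf
        else:
            inside = pos[(pos >= reg.start) & (pos < reg.end)]
            if len(inside):
                dist = 0.0
            else:
                mid = 0.5 * (reg.start + reg.end)
                i = np.searchsorted(pos, mid)
                cands = pos[max(0, i - 1) : i + 1]
                dist = float(np.min(np.abs(cands - mid)))
        bin_label = labels[int(np.searchsorted(breaks, dist, side="right"))]
        rows.append((reg.chrom, reg.start, reg.end, dist, bin_label))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "tss_distance", "bin"])
    if len(table):
        proportions = (
            table["bin"].value_counts(normalize=True).reindex(labels, fill_value=0.0)
        )
    else:
        proportions = pd.Series(0.0, index=labels, name="proportion")
    return table, proportions


def overlap_fraction(set_a, set_b) -> float:
    """|A intersect B| / |A|, by gene id for sets, by >=1 bp for intervals."""
    seq_a, seq_b = list(set_a), list(set_b)
    if len(seq_a) == 0:
        return 0.0
    if seq_a and isinstance(seq_a[0], (GenomicInterval, EnrichedRegion)):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in seq_b:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        hits = 0
        for iv in seq_a:
            for s, e in by_chrom.get(iv.chrom, ()):
                if iv.start < e and iv.end > s:
                    hits += 1
                    break
        return hits / len(seq_a)
    return len(set(seq_a) & set(seq_b)) / len(set(seq_a))
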