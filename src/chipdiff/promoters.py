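"""Promoter-level abundance, bimodal enrichment cutoffs, quartile classes,
and CpG density.

Promoter abundance is ``log2(mean count + 8)`` over TSS +- 1 kb, averaged
across libraries; the +8 prior keeps low-count promoters finite and
comparable across experiments. Enrichment cutoffs come from the local
minimum of the bimodal abundance density (Gaussian KDE); enriched promoters
are split into low / intermediate / high by the 25th/75th percentiles of the
enriched-set abundance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeDeclaration, TssAnnotation
from .windows import ReadsLike, WindowCountMatrix, fragments_frame

logger = logging.getLogger(__name__)


class BimodalityError(ValueError):
    """Raised when an abundance density has no usable bimodal structure."""


@dataclass(frozen=True)
class EnrichmentCutoff:
    mark: str
    cutoff: float
    provenance: str  # "bimodal_minimum" or "user_supplied"


def promoter_counts(
    read_sets: Mapping[str, ReadsLike],
    tss: TssAnnotation,
    genome: GenomeDeclaration,
    radius: int = 1000,
    fragment_length: int = 147,
) -> pd.DataFrame:
    """Mean fragment counts per promoter (TSS +- radius) across libraries.

    Returns gene_id, per-library counts, mean_count and
    ``log_abundance = log2(mean_count + 8)``.
    """
    prom = tss.promoters(radius)
    out = prom[["gene_id", "chrom", "start", "end"]].copy()
    per_lib = []
    for name, reads in read_sets.items():
        frags = fragments_frame(reads, genome, fragment_length)
        col = np.zeros(len(prom), dtype=np.int64)
        for chrom, sub in frags.groupby("chrom", sort=False):
            sel = prom["chrom"] == chrom
            if not sel.any():
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            p_start = prom.loc[sel, "start"].to_numpy()
            p_end = prom.loc[sel, "end"].to_numpy()
            # overlap iff frag.start < p_end and frag.end > p_start
            n_start_before_end = np.searchsorted(starts, p_end, side="left")
            n_end_before_start = np.searchsorted(ends, p_start, side="right")
            col[np.nonzero(sel.to_numpy())[0]] = n_start_before_end - n_end_before_start
        out[name] = col
        per_lib.append(name)
    out["mean_count"] = out[per_lib].mean(axis=1) if per_lib else 0.0
    out["log_abundance"] = np.log2(out["mean_count"] + 8.0)
    return out


def promoter_counts_from_matrix(
    matrix: WindowCountMatrix, tss: TssAnnotation, radius: int = 1000
) -> pd.DataFrame:
    """Promoter counts by summing window counts overlapping TSS +- radius."""
    prom = tss.promoters(radius)
    out = prom[["gene_id", "chrom", "start", "end"]].copy()
    counts = np.zeros((len(prom), len(matrix.samples)))
    for chrom, psub in prom.groupby("chrom", sort=False):
        wsel = matrix.windows["chrom"] == chrom
        if not wsel.any():
            continue
        wstart = matrix.windows.loc[wsel, "start"].to_numpy()
        wend = matrix.windows.loc[wsel, "end"].to_numpy()
        wrow = np.nonzero(wsel.to_numpy())[0]
        order = np.argsort(wstart)
        wstart, wend, wrow = wstart[order], wend[order], wrow[order]
        max_w = int((wend - wstart).max())
        for i, pr in psub.iterrows():
            lo = np.searchsorted(wstart, pr["start"] - max_w, side="left")
            hi = np.searchsorted(wstart, pr["end"], side="left")
            cand = np.arange(lo, hi)
            cand = cand[(wend[cand] > pr["start"]) & (wstart[cand] < pr["end"])]
            if len(cand):
                counts[prom.index.get_loc(i)] = matrix.counts[wrow[cand]].sum(axis=0)
    for j, name in enumerate(matrix.samples):
        out[name] = counts[:, j]
    out["mean_count"] = counts.mean(axis=1)
    out["log_abundance"] = np.log2(out["mean_count"] + 8.0)
    return out


def bimodal_cutoff(
    log_abundances: np.ndarray,
    mark: str = "",
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
    user_cutoff: Optional[float] = None,
    bandwidth_scale: float = 1.0,
) -> EnrichmentCutoff:
    """Enrichment cutoff at the local minimum of a bimodal KDE density.

    A Gaussian KDE (Silverman bandwidth by default, optionally rescaled by
    ``bandwidth_scale``) is evaluated on a ``grid_size``-point grid; the
    cutoff is the density argmin strictly between the two highest local
    maxima. A unimodal density raises :class:`BimodalityError`, instructing
    the caller to supply a cutoff by inspection (as is needed for
    distributions that do not follow a bimodal trend).
    """
    if user_cutoff is not None:
        return EnrichmentCutoff(mark, float(user_cutoff), "user_supplied")
    x = np.asarray(log_abundances, dtype=float)
    if len(x) < 200:
        raise ValueError("need >= 200 values for a stable density estimate")
    kde = stats.gaussian_kde(x, bw_method=bandwidth_rule)
    if bandwidth_scale != 1.0:
        kde.set_bandwidth(kde.factor * bandwidth_scale)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    maxima = interior[is_max]
    if len(maxima) < 2:
        raise BimodalityError(
            f"density for {mark or 'mark'} is not bimodal; supply user_cutoff "
            "after inspecting the distribution"
        )
    top2 = maxima[np.argsort(dens[maxima])[::-1][:2]]
    lo, hi = int(min(top2)), int(max(top2))
    between = np.arange(lo + 1, hi)
    if len(between) == 0:
        raise BimodalityError("modes are adjacent; no interior minimum")
    cutoff = float(grid[between[np.argmin(dens[between])]])
    logger.info("bimodal cutoff for %s at %.3f (KDE local minimum)", mark or "mark", cutoff)
    return EnrichmentCutoff(mark, cutoff, "bimodal_minimum")


def classify_enrichment(
    abundances: pd.DataFrame, cutoff: EnrichmentCutoff
) -> pd.DataFrame:
    """Assign unenriched / low / intermediate / high promoter classes.

    Promoters at or below the cutoff are unenriched. The enriched set is
    split at the 25th/75th percentiles of its log abundance: lowest quarter
    -> low, middle two quarters -> intermediate, top quarter -> high. Values
    exactly at a quartile boundary go to the inner (intermediate) class.
    """
    out = abundances.copy()
    vals = out["log_abundance"].to_numpy(dtype=float)
    enriched = vals > cutoff.cutoff
    cls = np.full(len(out), "unenriched", dtype=object)
    if not enriched.any():
        warnings.warn("no promoters above the enrichment cutoff")
    else:
        sub = vals[enriched]
        q25, q75 = np.percentile(sub, [25, 75])
        sub_cls = np.full(len(sub), "intermediate", dtype=object)
        sub_cls[sub < q25] = "low"
        sub_cls[sub > q75] = "high"
        cls[enriched] = sub_cls
    out["enriched"] = enriched
    out["enrichment_class"] = cls
    return out


def cpg_density(sequence: str) -> float:
    """Observed/expected CpG: (N_CpG / (N_C * N_G)) * L.

    Case-insensitive; ``L`` counts only unambiguous A/C/G/T letters. Returns
    0 when the sequence contains no C or no G.
    """
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    length = sum(seq.count(b) for b in "ACGT")
    return n_cg / (n_c * n_g) * length


def attach_cpg_density(
    abundances: pd.DataFrame, sequences: Mapping[str, str]
) -> pd.DataFrame:
    """Add a cpg_oe column from per-gene promoter sequences."""
    out = abundances.copy()
    out["cpg_oe"] = [
        cpg_density(sequences[g]) if g in sequences else np.nan
        for g in out["gene_id"]
    ]
    return out
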