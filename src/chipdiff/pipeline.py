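"""End-to-end pipeline orchestration with a manifest for reproducible runs.

Stages run in a fixed order — regions, normalize, qc, test, combine,
classify, overlaps, tracks — each writing TSV/BED output plus an entry in
``manifest.json`` recording parameters, seeds, excluded samples and row
counts. Re-running with the same config and inputs reproduces the outputs
byte-identically.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .coverage import coverage_rpkm
from .differential import DifferentialEnrichment
from .overlaps import call_bivalent, fisher_overlap, tss_distance_annotation
from .promoters import (
    BimodalityError,
    bimodal_cutoff,
    classify_enrichment,
    promoter_counts,
)
from .windows import (
    MARK_PROFILES,
    WindowGrid,
    call_regions,
    fragments_frame,
)

logger = logging.getLogger(__name__)

EXIT_MISSING_INPUT = 3
EXIT_PROFILE_MISMATCH = 4
EXIT_NOT_BIMODAL = 5

STAGES = ("regions", "normalize", "qc", "test", "combine",
          "classify", "overlaps", "tracks")


@dataclass
class LibrarySpec:
    name: str
    path: str
    condition: str


@dataclass
class RunConfig:
    """Everything one run needs; any override of profile defaults is logged."""

    profile: str
    libraries: list[LibrarySpec]
    genome: Mapping[str, int]
    tss_path: str
    out_dir: str
    contrast: tuple[str, str] = ("TG", "CRwt")
    blacklist_path: Optional[str] = None
    secondary_profile: Optional[str] = None
    secondary_libraries: list[LibrarySpec] = field(default_factory=list)
    alpha: float = 0.2
    radius: int = 1000
    span: float = 0.3
    top_k: int = 500
    outlier_c: float = 2.0
    drop_outliers: bool = True
    fragment_length: int = 147
    min_mapq: int = 20
    keep_duplicates: bool = True
    track_bin: int = 10
    seed: int = 0
    user_cutoff: Optional[float] = None
    secondary_user_cutoff: Optional[float] = None
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        d["libraries"] = [LibrarySpec(**lib) for lib in d["libraries"]]
        d["secondary_libraries"] = [
            LibrarySpec(**lib) for lib in d.get("secondary_libraries", [])
        ]
        if "contrast" in d:
            d["contrast"] = tuple(d["contrast"])
        return cls(**d)


def _load_reads(spec: LibrarySpec, config: RunConfig, genome) -> pd.DataFrame:
    path = Path(spec.path)
    if not path.exists():
        raise FileNotFoundError(f"missing input for library {spec.name}: {path}")
    records = gio.read_alignments(
        path, min_mapq=config.min_mapq,
        keep_duplicates=config.keep_duplicates, genome=genome,
    )
    frame = gio.reads_to_frame(records)
    if len(frame) and config.profile == "h3k27me3" and not frame["is_fragment"].any():
        logger.warning(
            "profile h3k27me3 expects paired-end fragments but %s is single-end; "
            "extending reads to %d bp", spec.name, config.fragment_length,
        )
    return frame


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the results directory."""
    if config.profile not in MARK_PROFILES:
        raise ValueError(f"unknown profile {config.profile!r}")
    profile = MARK_PROFILES[config.profile]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "profile": profile.__dict__,
        "contrast": list(config.contrast),
        "alpha": config.alpha,
        "seed": config.seed,
        "overrides": config.overrides,
        "excluded_samples": [],
        "stages": [],
    }
    genome = gio.GenomeDeclaration(config.genome)
    tss = gio.TssAnnotation.from_tsv(config.tss_path, genome=genome)
    blacklist = (
        gio.read_intervals(config.blacklist_path)
        if config.blacklist_path else []
    )
    grid = WindowGrid(genome, profile.window_width, excluded=blacklist)
    read_sets = {
        spec.name: _load_reads(spec, config, genome) for spec in config.libraries
    }
    design = {spec.name: spec.condition for spec in config.libraries}

    def done(stage: str, n_rows: int, **params) -> None:
        manifest["stages"].append({"stage": stage, "rows": int(n_rows), **params})

    # --- regions
    regions, matrix, keep, background = call_regions(
        read_sets, grid, profile, config.fragment_length
    )
    gio.write_intervals([r.to_interval() for r in regions], out / "regions.bed")
    matrix.windows.assign(keep=keep).to_csv(out / "window_filter.tsv", sep="\t", index=False)
    done("regions", len(regions), global_background=background.global_background,
         n_windows=int(matrix.n_windows), n_kept=int(keep.sum()))

    # --- normalize + qc + test (the differential model)
    filtered = matrix.subset(keep)
    model = DifferentialEnrichment(filtered, design, promoters=tss,
                                   span=config.span, radius=config.radius)
    results = model.fit(config.contrast, alpha=config.alpha,
                        top_k=config.top_k, outlier_c=config.outlier_c)
    done("normalize", filtered.n_windows, span=config.span,
         refine_iterations=results.refine_iterations)
    if results.mds.outliers and config.drop_outliers:
        manifest["excluded_samples"] = list(results.mds.outliers)
        model = model.drop_samples(results.mds.outliers)
        results = model.fit(config.contrast, alpha=config.alpha,
                            top_k=config.top_k, outlier_c=config.outlier_c)
    pd.DataFrame(
        results.mds.coordinates, index=results.mds.samples, columns=["dim1", "dim2"]
    ).to_csv(out / "mds.tsv", sep="\t")
    done("qc", len(results.mds.samples), outliers=manifest["excluded_samples"],
         outlier_c=config.outlier_c)
    results.window_results.to_csv(out / "window_tests.tsv", sep="\t", index=False)
    done("test", len(results.window_results))

    # --- combine (Simes + BH at promoters)
    promoter_results = results.combine_promoters()
    promoter_results.to_csv(out / "promoter_tests.tsv", sep="\t", index=False)
    done("combine", len(promoter_results), radius=config.radius,
         alpha=config.alpha,
         n_differential=int(promoter_results["is_differential"].sum()))

    # --- classify (promoter abundance classes, primary mark)
    prom_counts = promoter_counts(read_sets, tss, genome, config.radius,
                                  config.fragment_length)
    try:
        cutoff = bimodal_cutoff(
            prom_counts["log_abundance"].to_numpy(), mark=config.profile,
            user_cutoff=config.user_cutoff,
        )
    except BimodalityError:
        raise SystemExit(EXIT_NOT_BIMODAL)
    classified = classify_enrichment(prom_counts, cutoff)
    class_cols = ["gene_id", "mean_count", "log_abundance", "enriched",
                  "enrichment_class"]
    classified[class_cols].to_csv(out / "promoter_classes.tsv", sep="\t", index=False)
    done("classify", len(classified), cutoff=cutoff.cutoff,
         provenance=cutoff.provenance)

    # --- overlaps (TSS distances; bivalency if a secondary mark is given)
    dist_table, proportions = tss_distance_annotation(regions, tss)
    dist_table.to_csv(out / "region_tss_distance.tsv", sep="\t", index=False)
    proportions.rename("proportion").to_csv(out / "tss_distance_bins.tsv", sep="\t")
    overlap_info: dict = {"tss_bins": proportions.to_dict()}
    if config.secondary_libraries:
        sec_reads = {
            spec.name: _load_reads(spec, config, genome)
            for spec in config.secondary_libraries
        }
        sec_counts = promoter_counts(sec_reads, tss, genome, config.radius,
                                     config.fragment_length)
        sec_cutoff = bimodal_cutoff(
            sec_counts["log_abundance"].to_numpy(),
            mark=config.secondary_profile or "secondary",
            user_cutoff=config.secondary_user_cutoff,
        )
        sec_classified = classify_enrichment(sec_counts, sec_cutoff)
        bivalency = call_bivalent(classified, sec_classified)
        bivalency.to_csv(out / "bivalency.tsv", sep="\t", index=False)
        universe = set(classified.loc[classified["enriched"], "gene_id"])
        diff_genes = set(
            promoter_results.loc[promoter_results["is_differential"], "gene_id"]
        )
        fisher = fisher_overlap(
            diff_genes & universe,
            set(bivalency.loc[bivalency["bivalent"], "gene_id"]) & universe,
            universe=universe,
        )
        overlap_info["bivalent_fisher"] = {
            "odds_ratio": fisher.odds_ratio, "p_value": fisher.p_value,
            "table": fisher.table.__dict__,
            "universe": "promoters enriched for the primary mark",
        }
    done("overlaps", len(dist_table), **overlap_info)

    # --- tracks
    for spec in config.libraries:
        track = coverage_rpkm(read_sets[spec.name], genome, config.track_bin,
                              config.fragment_length, library=spec.name)
        track.to_bedgraph(out / f"{spec.name}.bedgraph")
    done("tracks", len(config.libraries), bin_width=config.track_bin)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
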