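"""Shared fixtures: toy genomes/files and the expensive simulated datasets.

The read-level default simulation and the 50-run null-calibration study are
session-scoped because several tests (including the acceptance suite) share
them.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chipdiff as cd
from chipdiff.differential import DifferentialEnrichment


@pytest.fixture
def toy_genome() -> cd.GenomeDeclaration:
    return cd.GenomeDeclaration({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def toy_sam(tmp_path, toy_genome):
    """5-record single-end SAM, one duplicate-flagged, mapq {20, 21, 30}."""
    path = tmp_path / "toy.sam"
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        "@SQ\tSN:chr1\tLN:100000",
        "@SQ\tSN:chr2\tLN:50000",
        # name flag chrom pos mapq cigar rnext pnext tlen seq qual
        "r1\t0\tchr1\t101\t30\t100M\t*\t0\t0\t*\t*",
        "r2\t16\tchr1\t201\t21\t100M\t*\t0\t0\t*\t*",
        "r3\t0\tchr1\t301\t20\t100M\t*\t0\t0\t*\t*",  # fails mapq > 20
        "r4\t1024\tchr1\t401\t30\t100M\t*\t0\t0\t*\t*",  # duplicate
        "r5\t0\tchr2\t501\t55\t100M\t*\t0\t0\t*\t*",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def default_dataset() -> cd.SimulatedDataset:
    """Read-level default simulation: the study conditions."""
    return cd.simulate_reads(cd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Full read-level analysis of the default dataset (both contrasts)."""
    ds = default_dataset
    k4_reads = {n: ds.filtered_reads(n) for n in ds.reads if n.startswith("k4")}
    grid = cd.WindowGrid(ds.genome, 150)
    regions, matrix, keep, background = cd.call_regions(
        k4_reads, grid, cd.MARK_PROFILES["h3k4me3"]
    )
    filt = matrix.subset(keep)
    design = {n: n.split("_")[1] for n in filt.samples}
    out = {"dataset": ds, "regions": regions, "matrix": matrix, "keep": keep,
           "background": background, "k4_reads": k4_reads}
    for cond in ("TG", "nonTG"):
        names = [n for n in filt.samples if design[n] in ("CRwt", cond)]
        model = DifferentialEnrichment(
            filt.subset_samples(names), {n: design[n] for n in names},
            promoters=ds.tss,
        )
        res = model.fit((cond, "CRwt"))
        out[f"results_{cond}"] = res
        out[f"promoters_{cond}"] = res.combine_promoters()
    return out


def _null_config(seed: int, **kwargs) -> cd.SimulationConfig:
    return cd.SimulationConfig(
        seed=seed, n_promoters=600, n_differential_tg=0, n_differential_nontg=0,
        **kwargs,
    )


@pytest.fixture(scope="session")
def null_study():
    """50 seeded null simulations (planted IP bias, no differential), each
    analysed with and without loess normalization."""
    records = []
    for seed in range(50):
        cfg = _null_config(2000 + seed)
        matrix, truth, libs = cd.simulate_window_counts(cfg)
        tss = cd.simulate_annotation(cfg, truth)[1]
        names = [n for n in matrix.samples if n.split("_")[1] in ("CRwt", "TG")]
        sub = matrix.subset_samples(names)
        design = {n: n.split("_")[1] for n in names}
        row = {"seed": seed}
        for norm in (True, False):
            model = DifferentialEnrichment(sub, design, promoters=tss, normalize=norm)
            res = model.fit(("TG", "CRwt"), refine_normalization=norm)
            prom = res.combine_promoters()
            key = "loess" if norm else "raw"
            row[f"calls_{key}"] = int(prom["is_differential"].sum())
        records.append(row)
    return pd.DataFrame(records)
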