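"""Synthetic sperm ChIP-seq datasets with ground truth.

The generator emulates the statistical architecture the analysis assumes:

* promoter-anchored H3K4me3 with a bimodal (two log-normal component)
  abundance distribution over promoters;
* H3K27me3 at a promoter subset, with a bivalent subset carrying both marks;
* condition-specific differential promoters (a TG set and a partially
  overlapping nonTG set, gains favoured) with stated log2 effect sizes;
* a smooth, monotone, library-specific IP-efficiency bias acting on expected
  log-counts (the non-linear distortion loess normalization must remove);
* replicate-level negative-binomial noise, optionally with one replicate's
  dispersion inflated tenfold (the planted MDS outlier);
* uniform genome-wide background fragments and a small fraction of
  low-MAPQ reads that the alignment filter must drop.

Everything derives deterministically from one seed; each library draws from
its own substream keyed by the library name, so adding a library never
perturbs the others.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import GenomeDeclaration, TssAnnotation
from .windows import WindowCountMatrix

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic datasets."""

    seed: int = 1
    genome: Mapping[str, int] = field(default_factory=lambda: {"chr1": 12_000_000})
    n_promoters: int = 2000
    tss_min_spacing: int = 5000
    frac_k4: float = 0.55
    frac_k27: float = 0.25
    frac_bivalent: float = 0.15
    # two log-normal abundance components (log2 expected fragments/promoter)
    enriched_mean_log2: float = 9.0
    enriched_sd_log2: float = 1.0
    unenriched_mean_log2: float = 2.0
    unenriched_sd_log2: float = 0.8
    conditions: tuple[str, ...] = ("CRwt", "TG", "nonTG")
    n_replicates: int = 3
    k27_replicates: int = 2
    n_differential_tg: int = 300
    n_differential_nontg: int = 100
    nontg_overlap: float = 0.75
    lfc_low: float = 1.0
    lfc_high: float = 3.0
    frac_gain: float = 0.8
    bivalent_diff_weight: float = 0.2
    dispersion: float = 0.05
    outlier_replicate: Optional[str] = None
    outlier_dispersion_factor: float = 10.0
    background_rate_per_kb: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.4)
    # IP-efficiency bias: a condition-shared (batch) component plus an
    # independent per-library component, both monotone-smooth in abundance
    bias_amplitude_condition: float = 1.0
    bias_amplitude_library: float = 0.5
    bias_center: float = 6.0
    bias_scale: float = 1.5
    fragment_length: int = 147
    read_length: int = 100
    mapq_fail_rate: float = 0.02
    promoter_radius: int = 1000

    def __post_init__(self) -> None:
        for name in ("frac_k4", "frac_k27", "frac_bivalent", "nontg_overlap", "frac_gain"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_bivalent > min(self.frac_k4, self.frac_k27):
            raise ValueError("frac_bivalent cannot exceed either mark fraction")
        needed = self.n_promoters * self.tss_min_spacing
        if sum(self.genome.values()) < needed:
            raise ValueError(
                f"genome too small for {self.n_promoters} promoters at "
                f">={self.tss_min_spacing} bp spacing"
            )


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


@dataclass
class LibraryDesign:
    name: str
    mark: str
    condition: str
    replicate: str
    size_factor: float
    bias_amp: float
    dispersion: float


def library_table(config: SimulationConfig) -> pd.DataFrame:
    """Per-library design: size factors, bias amplitudes, dispersions."""
    rng = _rng(config, "libraries")
    rows = []
    letters = "ABCDEFGH"
    specs = [("k4", c, letters[r]) for c in config.conditions
             for r in range(config.n_replicates)]
    specs += [("k27", "CRwt", letters[r]) for r in range(config.k27_replicates)]
    lo, hi = config.library_size_range
    cond_amp = {
        (mark, cond): float(rng.uniform(-config.bias_amplitude_condition,
                                        config.bias_amplitude_condition))
        for mark in ("k4", "k27") for cond in config.conditions
    }
    for mark, cond, rep in specs:
        name = f"{mark}_{cond}_{rep}"
        size = float(rng.uniform(lo, hi))
        amp = cond_amp[(mark, cond)] + float(
            rng.uniform(-config.bias_amplitude_library, config.bias_amplitude_library)
        )
        phi = config.dispersion
        if config.outlier_replicate == name:
            phi *= config.outlier_dispersion_factor
        rows.append((name, mark, cond, rep, size, amp, phi))
    return pd.DataFrame(
        rows, columns=["name", "mark", "condition", "replicate",
                       "size_factor", "bias_amp", "dispersion"],
    )


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Planted per-promoter architecture (flags, components, effect sizes)."""
    rng = _rng(config, "truth")
    n = config.n_promoters
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    # enrichment flags: bivalent promoters first, then mark-only promoters
    idx = rng.permutation(n)
    n_biv = int(round(config.frac_bivalent * n))
    n_k4 = int(round(config.frac_k4 * n))
    n_k27 = int(round(config.frac_k27 * n))
    k4 = np.zeros(n, bool)
    k27 = np.zeros(n, bool)
    biv = np.zeros(n, bool)
    biv[idx[:n_biv]] = True
    k4[idx[:n_k4]] = True  # first n_biv of these are the bivalent ones
    k27[idx[:n_biv]] = True
    k27[idx[n_k4 : n_k4 + (n_k27 - n_biv)]] = True
    lam_k4 = np.where(
        k4,
        2.0 ** rng.normal(config.enriched_mean_log2, config.enriched_sd_log2, n),
        2.0 ** rng.normal(config.unenriched_mean_log2, config.unenriched_sd_log2, n),
    )
    lam_k27 = np.where(
        k27,
        2.0 ** rng.normal(config.enriched_mean_log2, config.enriched_sd_log2, n),
        2.0 ** rng.normal(config.unenriched_mean_log2, config.unenriched_sd_log2, n),
    )
    # differential promoters live among k4-enriched ones; bivalent promoters
    # are down-weighted (the planted depletion of bivalent loci)
    cand = np.nonzero(k4)[0]
    n_tg = min(config.n_differential_tg, len(cand))
    if n_tg > 0:
        weights = np.where(biv[cand], config.bivalent_diff_weight, 1.0)
        tg_set = rng.choice(cand, size=n_tg, replace=False,
                            p=weights / weights.sum())
    else:
        tg_set = np.array([], dtype=int)
    diff_tg = np.zeros(n, bool)
    diff_tg[tg_set] = True
    n_shared = int(round(config.nontg_overlap * config.n_differential_nontg))
    n_shared = min(n_shared, n_tg)
    shared = rng.choice(tg_set, size=n_shared, replace=False)
    rest = np.setdiff1d(cand, tg_set)
    n_new = min(config.n_differential_nontg - n_shared, len(rest))
    diff_nontg = np.zeros(n, bool)
    diff_nontg[shared] = True
    if n_new > 0:
        w_rest = np.where(biv[rest], config.bivalent_diff_weight, 1.0)
        new = rng.choice(rest, size=n_new, replace=False, p=w_rest / w_rest.sum())
        diff_nontg[new] = True

    def draw_lfc(mask):
        out = np.zeros(n)
        k = int(mask.sum())
        mag = rng.uniform(config.lfc_low, config.lfc_high, k)
        sign = np.where(rng.random(k) < config.frac_gain, 1.0, -1.0)
        out[mask] = mag * sign
        return out

    lfc_tg = draw_lfc(diff_tg)
    lfc_nontg = np.zeros(n)
    # shared promoters shift in the same direction in nonTG (the inherited set)
    lfc_nontg[diff_nontg] = rng.uniform(config.lfc_low, config.lfc_high, int(diff_nontg.sum()))
    lfc_nontg[diff_nontg] *= np.where(
        rng.random(int(diff_nontg.sum())) < config.frac_gain, 1.0, -1.0
    )
    lfc_nontg[diff_tg & diff_nontg] = np.sign(lfc_tg[diff_tg & diff_nontg]) * np.abs(
        lfc_nontg[diff_tg & diff_nontg]
    )
    return pd.DataFrame({
        "gene_id": gene_ids,
        "k4": k4, "k27": k27, "bivalent": biv,
        "lambda_k4": lam_k4, "lambda_k27": lam_k27,
        "diff_tg": diff_tg, "lfc_tg": lfc_tg,
        "diff_nontg": diff_nontg, "lfc_nontg": lfc_nontg,
    })


def simulate_annotation(
    config: SimulationConfig, truth: Optional[pd.DataFrame] = None
) -> tuple[GenomeDeclaration, TssAnnotation, dict[str, str]]:
    """Genome declaration, TSS table (>= min spacing apart) and promoter
    sequences, with elevated CpG density at enriched promoters."""
    if truth is None:
        truth = simulate_truth(config)
    rng = _rng(config, "annotation")
    genome = GenomeDeclaration(config.genome)
    chroms = genome.chromosomes
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    per_chrom = np.maximum(
        np.round(lengths / lengths.sum() * config.n_promoters).astype(int), 0
    )
    while per_chrom.sum() != config.n_promoters:
        per_chrom[int(np.argmax(lengths))] += config.n_promoters - per_chrom.sum()
    rows = []
    gi = 0
    spacing = config.tss_min_spacing
    for chrom, length, k in zip(chroms, lengths, per_chrom):
        if k == 0:
            continue
        margin = config.promoter_radius + config.fragment_length
        slot = (length - 2 * margin) / k
        if slot < spacing:
            raise ValueError(f"cannot place {k} TSSs on {chrom} at >={spacing} bp spacing")
        jitter = rng.uniform(0, max(slot - spacing, 1), k)
        pos = margin + np.arange(k) * slot + jitter
        for p in pos:
            rows.append((truth["gene_id"].iloc[gi], chrom, int(p),
                         "+" if rng.random() < 0.5 else "-"))
            gi += 1
    tss = TssAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]), genome=genome
    )
    # promoter sequences: first-order Markov chain with elevated P(G | C) at
    # enriched promoters so observed/expected CpG separates the classes
    seqs: dict[str, str] = {}
    enriched = (truth["k4"] | truth["k27"]).to_numpy()
    L = 2 * config.promoter_radius
    for i, gene in enumerate(truth["gene_id"]):
        if enriched[i]:
            freqs = np.array([0.25, 0.25, 0.25, 0.25])
            p_g_after_c = 0.20  # obs/exp ~ 0.8 (CpG-island-like)
        else:
            freqs = np.array([0.29, 0.21, 0.21, 0.29])
            p_g_after_c = 0.05  # obs/exp ~ 0.25 (CpG-depleted bulk)
        seq = BASES[rng.choice(4, size=L, p=freqs)]
        # letters following a C are redrawn with P(G) = p_g_after_c so the
        # observed/expected CpG ratio hits the target for the class
        after_c = np.roll(seq == "C", 1)
        after_c[0] = False
        k = int(after_c.sum())
        other = freqs.copy()
        other[2] = 0.0
        other = other / other.sum() * (1.0 - p_g_after_c)
        other[2] = p_g_after_c
        seq[after_c] = BASES[rng.choice(4, size=k, p=other)]
        seqs[gene] = "".join(seq)
    return genome, tss, seqs


def _condition_rates(
    config: SimulationConfig, truth: pd.DataFrame, lib: pd.Series
) -> np.ndarray:
    """Per-promoter expected rates for a library's condition (no bias/size)."""
    lam = truth["lambda_k4" if lib["mark"] == "k4" else "lambda_k27"].to_numpy().copy()
    if lib["mark"] == "k4":
        if lib["condition"] == "TG":
            lam = lam * 2.0 ** truth["lfc_tg"].to_numpy()
        elif lib["condition"] == "nonTG":
            lam = lam * 2.0 ** truth["lfc_nontg"].to_numpy()
    return lam


def _apply_bias(config: SimulationConfig, lib: pd.Series, rates: np.ndarray) -> np.ndarray:
    """IP-efficiency distortion: monotone smooth function of the local
    (window- or promoter-level) expected log2 rate."""
    a = np.log2(np.maximum(rates, 1e-9))
    bias = lib["bias_amp"] / (1.0 + np.exp(-(a - config.bias_center) / config.bias_scale))
    return rates * lib["size_factor"] * 2.0**bias


def _expected_counts(
    config: SimulationConfig, truth: pd.DataFrame, lib: pd.Series
) -> np.ndarray:
    """Per-promoter expected fragment counts for one library (bias applied)."""
    return _apply_bias(config, lib, _condition_rates(config, truth, lib))


def simulate_promoter_counts(
    config: SimulationConfig, truth: pd.DataFrame, libraries: pd.DataFrame
) -> pd.DataFrame:
    """Realized NB promoter counts per library (columns = library names)."""
    out = {}
    for _, lib in libraries.iterrows():
        rng = _rng(config, f"counts:{lib['name']}")
        mu = _expected_counts(config, truth, lib)
        phi = lib["dispersion"]
        out[lib["name"]] = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    return pd.DataFrame(out, index=truth["gene_id"])


def _promoter_windows(
    config: SimulationConfig, prom: pd.DataFrame, window_width: int = 150
) -> pd.DataFrame:
    """Tiling windows overlapping each promoter, with the interval of
    fragment start positions that overlap the window (lo, hi) and the
    fraction of the promoter's fragments expected to land there (weight)."""
    frag = config.fragment_length
    span = 2 * config.promoter_radius
    rows = []
    for i, pr in prom.iterrows():
        first = int(pr["start"]) // window_width
        last = (int(pr["end"]) - 1) // window_width
        for w in range(first, last + 1):
            w0, w1 = w * window_width, (w + 1) * window_width
            lo = max(int(pr["start"]), w0 - frag + 1)
            hi = min(int(pr["end"]), w1)
            weight = max(hi - lo, 0) / span
            if weight > 0:
                rows.append((pr["chrom"], w0, w1, i, lo, hi, weight))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "promoter", "lo", "hi", "weight"]
    )


def simulate_window_counts(
    config: SimulationConfig,
    truth: Optional[pd.DataFrame] = None,
    mark: str = "k4",
    window_width: int = 150,
) -> tuple[WindowCountMatrix, pd.DataFrame, pd.DataFrame]:
    """Count-level shortcut: a WindowCountMatrix over enriched-promoter
    windows, as the counting stage would produce after filtering.

    Each window's count is drawn independently as NB with mean equal to the
    promoter rate thinned by the window's fragment-overlap probability
    (thinning preserves the dispersion). The read-level path induces mild
    within-promoter correlation instead; marginals agree.
    """
    if truth is None:
        truth = simulate_truth(config)
    libs = library_table(config)
    libs = libs[libs["mark"] == mark].reset_index(drop=True)
    genome, tss, _ = simulate_annotation(config, truth)
    enriched = truth[mark].to_numpy()
    prom = tss.promoters(config.promoter_radius).loc[enriched].reset_index(drop=True)
    tr = truth.loc[enriched].reset_index(drop=True)
    wdf = _promoter_windows(config, prom, window_width)
    counts = np.zeros((len(wdf), len(libs)), dtype=np.int64)
    pidx = wdf["promoter"].to_numpy()
    weights = wdf["weight"].to_numpy()
    lib_sizes = np.zeros(len(libs))
    total_rate = truth["lambda_k4" if mark == "k4" else "lambda_k27"].sum()
    for j, (_, lib) in enumerate(libs.iterrows()):
        rng = _rng(config, f"wincounts:{lib['name']}")
        rates = _condition_rates(config, tr, lib)
        mu = _apply_bias(config, lib, rates[pidx] * weights)
        phi = lib["dispersion"]
        counts[:, j] = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        background = config.background_rate_per_kb * genome.total_length() / 1000.0
        lib_sizes[j] = max(
            counts[:, j].sum(),
            total_rate * lib["size_factor"] + background * lib["size_factor"],
        )
    matrix = WindowCountMatrix(
        windows=wdf[["chrom", "start", "end"]].copy(),
        counts=counts, samples=list(libs["name"]), library_sizes=lib_sizes,
    )
    # emulate the enrichment filter the counting stage applies: drop windows
    # not clearing the global background by the mark's log2 fold-change
    bg_count = (
        config.background_rate_per_kb
        * (window_width + config.fragment_length - 1) / 1000.0
        * libs["size_factor"].to_numpy()
    )
    global_bg = float(np.mean(np.log2((bg_count + 0.5) / (lib_sizes + 1.0) * 1e6)))
    min_log2fc = 5.0 if mark == "k4" else 7.0
    keep = matrix.abundance() - global_bg > min_log2fc
    return matrix.subset(keep), truth, libs


def simulate_reads(
    config: SimulationConfig, truth: Optional[pd.DataFrame] = None
) -> "SimulatedDataset":
    """Full read-level simulation for every library in the design.

    H3K4me3 libraries are single-end ``read_length`` reads (the counter must
    extend them to the fragment length); H3K27me3 libraries are emitted as
    collapsed paired-end fragments. About ``mapq_fail_rate`` of reads get
    MAPQ <= 20 and must be removed by the alignment filter.
    """
    if truth is None:
        truth = simulate_truth(config)
    libs = library_table(config)
    genome, tss, seqs = simulate_annotation(config, truth)
    frag, rl = config.fragment_length, config.read_length
    reads: dict[str, pd.DataFrame] = {}
    prom = tss.promoters(config.promoter_radius)
    wdf = _promoter_windows(config, prom)
    w_chrom = wdf["chrom"].to_numpy()
    w_lo = wdf["lo"].to_numpy()
    w_hi = wdf["hi"].to_numpy()
    w_weight = wdf["weight"].to_numpy()
    w_pidx = wdf["promoter"].to_numpy()
    for _, lib in libs.iterrows():
        rng = _rng(config, f"reads:{lib['name']}")
        rates = _condition_rates(config, truth, lib)
        mu = _apply_bias(config, lib, rates[w_pidx] * w_weight)
        phi = lib["dispersion"]
        y = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        total = int(y.sum())
        p_chrom = np.repeat(w_chrom, y)
        lo = np.repeat(w_lo, y)
        hi = np.repeat(w_hi, y)
        fstart = (lo + rng.random(total) * (hi - lo)).astype(np.int64)
        chroms = [p_chrom]
        starts = [fstart]
        for chrom, length in genome.items():
            n_bg = rng.poisson(
                config.background_rate_per_kb * length / 1000.0 * lib["size_factor"]
            )
            chroms.append(np.full(n_bg, chrom, dtype=object))
            starts.append(rng.integers(0, max(length - frag, 1), n_bg))
        chrom_all = np.concatenate(chroms)
        fs = np.concatenate(starts)
        n = len(fs)
        for c, length in genome.items():
            m = chrom_all == c
            fs[m] = np.clip(fs[m], 0, max(length - frag, 0))
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        mapq = np.where(
            rng.random(n) < config.mapq_fail_rate,
            rng.integers(0, 21, n),
            rng.integers(21, 61, n),
        )
        if lib["mark"] == "k27":
            df = pd.DataFrame({
                "chrom": chrom_all, "start": fs, "end": fs + frag,
                "strand": strand, "mapq": mapq, "is_fragment": True,
            })
        else:
            rstart = np.where(strand == "+", fs, fs + frag - rl)
            df = pd.DataFrame({
                "chrom": chrom_all, "start": rstart, "end": rstart + rl,
                "strand": strand, "mapq": mapq, "is_fragment": False,
            })
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        reads[lib["name"]] = df
    return SimulatedDataset(config=config, genome=genome, tss=tss, sequences=seqs,
                            truth=truth, libraries=libs, reads=reads)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeDeclaration
    tss: TssAnnotation
    sequences: dict[str, str]
    truth: pd.DataFrame
    libraries: pd.DataFrame
    reads: dict[str, pd.DataFrame]

    def filtered_reads(self, name: str, min_mapq: int = 20) -> pd.DataFrame:
        df = self.reads[name]
        return df[df["mapq"] > min_mapq].reset_index(drop=True)

    def write_sam(self, name: str, path) -> None:
        write_sam(self.reads[name], self.genome, path,
                  read_length=self.config.read_length)

    def write_read_bed(self, name: str, path) -> None:
        df = self.reads[name]
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tread\t{row.mapq}\t{row.strand}\n")

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def write_sam(reads: pd.DataFrame, genome: GenomeDeclaration, path,
              read_length: int = 100) -> None:
    """Write a read table as plain SAM (paired fragments become proper pairs)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, row in enumerate(reads.itertuples(index=False)):
            if row.is_fragment:
                tlen = row.end - row.start
                mate = row.start + tlen - read_length
                fh.write(
                    f"frag{i}\t99\t{row.chrom}\t{row.start + 1}\t{row.mapq}\t"
                    f"{read_length}M\t=\t{mate + 1}\t{tlen}\t*\t*\n"
                )
                fh.write(
                    f"frag{i}\t147\t{row.chrom}\t{mate + 1}\t{row.mapq}\t"
                    f"{read_length}M\t=\t{row.start + 1}\t{-tlen}\t*\t*\n"
                )
            else:
                flag = 16 if row.strand == "-" else 0
                fh.write(
                    f"read{i}\t{flag}\t{row.chrom}\t{row.start + 1}\t{row.mapq}\t"
                    f"{row.end - row.start}M\t*\t0\t0\t*\t*\n"
                )
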