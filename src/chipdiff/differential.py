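"""Differential window enrichment: loess MA normalization, MDS QC,
negative-binomial window tests, Simes promoter combination, BH FDR.

The model is organised statsmodels-style: :class:`DifferentialEnrichment` is
built from a filtered :class:`~chipdiff.windows.WindowCountMatrix` and a
design (condition label per library); ``fit()`` estimates normalization
offsets and dispersions and tests a two-condition contrast per window,
returning a :class:`DifferentialEnrichmentResults` that carries the window
table, the offsets, MDS diagnostics and the promoter-level Simes/BH caller.

Per-window inference
--------------------
Counts follow a negative binomial GLM ``log mu_ij = beta_{g(j)} + log N_j +
log(2) * o_ij`` with library sizes ``N_j`` and loess offsets ``o_ij`` (log2
scale). Dispersions are profiled on a grid with the Cox-Reid adjustment,
summarised as an abundance trend by maximising the summed adjusted profile
likelihood within abundance bins, and per-window values are shrunk toward
the trend on the log scale (prior_df controls the strength; the default is
deliberately strong so the chi-square reference for the likelihood-ratio
test stays honest at 2-3 replicates per group). The condition effect is
tested by a 1-df likelihood-ratio test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm

from .io import TssAnnotation
from .windows import WindowCountMatrix

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# MA values and loess normalization


def ma_values(
    matrix: WindowCountMatrix,
    library: str,
    reference: Optional[np.ndarray] = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-window M (log2 ratio vs reference) and A (average abundance).

    The default reference is the geometric-mean pseudo-library: the mean
    log2-CPM across all samples. ``A`` is that same average abundance.
    """
    log2cpm = matrix.log2_cpm(prior_count)
    if reference is None:
        reference = log2cpm.mean(axis=1)
    j = matrix.samples.index(library)
    return pd.DataFrame({"M": log2cpm[:, j] - reference, "A": reference})


def loess_normalize(
    matrix: WindowCountMatrix,
    span: float = 0.3,
    iterations: int = 2,
    prior_count: float = 0.5,
    subset: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Loess (local-linear, tricube) normalization offsets, log2 scale.

    Fits each library's M-vs-A trend under the assumption that most windows
    are not differentially enriched, then row-centres the fitted offsets so
    they shift no per-window mean. Subtracting the offsets from log2-CPM (or
    supplying them to the NB tests) removes non-linear, abundance-dependent
    efficiency bias that linear scaling cannot touch.

    ``subset`` (boolean mask) restricts the windows the trend is *fitted* on;
    offsets for the remaining windows are interpolated along A. The
    normalization-refinement loop uses this to exclude windows already
    called differential from the fit.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    log2cpm = matrix.log2_cpm(prior_count)
    a = log2cpm.mean(axis=1)
    fit_mask = np.ones(matrix.n_windows, bool) if subset is None else np.asarray(subset)
    n_fit = int(fit_mask.sum())
    if n_fit * span < 10:
        raise ValueError(
            f"too few windows ({n_fit}) for span {span}; increase the span"
        )
    a_fit = a[fit_mask]
    order = np.argsort(a_fit)
    offsets = np.empty_like(log2cpm)
    delta = 0.01 * (a_fit.max() - a_fit.min()) if n_fit > 5000 else 0.0
    for j in range(log2cpm.shape[1]):
        m = (log2cpm[fit_mask, j] - a_fit)
        fitted = sm.nonparametric.lowess(
            m, a_fit, frac=span, it=iterations, delta=delta, return_sorted=False
        )
        offsets[:, j] = np.interp(a, a_fit[order], fitted[order])
    offsets -= offsets.mean(axis=1, keepdims=True)
    return offsets


# ---------------------------------------------------------------------------
# MDS QC


@dataclass
class MdsResult:
    samples: list[str]
    distances: np.ndarray  # pairwise leading-log2FC distances
    coordinates: np.ndarray  # (n_samples, 2) classical MDS embedding
    outliers: list[str]
    outlier_c: float


def mds_qc(
    matrix: WindowCountMatrix,
    offsets: Optional[np.ndarray] = None,
    top_k: int = 500,
    outlier_c: float = 2.0,
    prior_count: float = 0.5,
) -> MdsResult:
    """Leading-log2FC MDS of normalized libraries with outlier flagging.

    The distance between two libraries is the root-mean-square of the
    ``top_k`` largest absolute log2 fold changes between their normalized
    log2-CPM profiles. A library is flagged as an outlier when its median
    distance to all others exceeds ``outlier_c`` times the overall median
    pairwise distance.
    """
    ns = len(matrix.samples)
    if ns < 3:
        raise ValueError("MDS QC needs at least 3 samples")
    expr = matrix.log2_cpm(prior_count)
    if offsets is not None:
        expr = expr - offsets
    k = min(top_k, matrix.n_windows)
    dist = np.zeros((ns, ns))
    for u in range(ns):
        for v in range(u + 1, ns):
            diff = np.abs(expr[:, u] - expr[:, v])
            top = np.partition(diff, len(diff) - k)[len(diff) - k :]
            d = float(np.sqrt(np.mean(top**2)))
            dist[u, v] = dist[v, u] = d
    # classical MDS: double-centred squared distances, top-2 eigenvectors
    d2 = dist**2
    j = np.eye(ns) - np.ones((ns, ns)) / ns
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:2]
    coords = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    offdiag = dist[np.triu_indices(ns, 1)]
    overall = float(np.median(offdiag))
    outliers = []
    for u in range(ns):
        others = np.delete(dist[u], u)
        if overall > 0 and float(np.median(others)) > outlier_c * overall:
            outliers.append(matrix.samples[u])
    if outliers:
        logger.warning("MDS QC flagged outlier sample(s): %s", ", ".join(outliers))
    return MdsResult(samples=list(matrix.samples), distances=dist,
                     coordinates=coords, outliers=outliers, outlier_c=outlier_c)


# ---------------------------------------------------------------------------
# Negative binomial machinery (vectorized across windows)


def _nb_loglik(y, mu, phi):
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    )


def _fit_group_means(y, s, phi, groups, n_iter=30, tol=1e-10):
    """Newton fit of per-window, per-group NB log-means with offsets.

    ``y``: (n_windows, n_samples) counts, ``s``: multiplicative offsets
    (library size x 2^loess offset), ``phi``: (n_windows,) dispersions,
    ``groups``: integer label per sample. Returns ``beta`` (n_windows,
    n_groups) and the per-group expected information at the optimum.
    All-zero groups get beta = -inf (mu = 0).
    """
    glabels = np.unique(groups)
    nw = y.shape[0]
    beta = np.full((nw, len(glabels)), -np.inf)
    info = np.zeros((nw, len(glabels)))
    for gi, g in enumerate(glabels):
        cols = np.nonzero(groups == g)[0]
        yg, sg = y[:, cols], s[:, cols]
        tot = yg.sum(axis=1)
        pos = tot > 0
        b = np.log(np.maximum(tot[pos], 0.5) / sg[pos].sum(axis=1))
        phig = phi[pos]
        for _ in range(n_iter):
            mu = sg[pos] * np.exp(b)[:, None]
            w = 1.0 + phig[:, None] * mu
            score = ((yg[pos] - mu) / w).sum(axis=1)
            inf = np.maximum((mu / w).sum(axis=1), 1e-12)
            step = np.clip(score / inf, -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step), initial=0.0) < tol:
                break
        beta[pos, gi] = b
        mu = sg[pos] * np.exp(b)[:, None]
        info[pos, gi] = (mu / (1.0 + phig[:, None] * mu)).sum(axis=1)
    return beta, info


def _loglik_groups(y, s, phi, groups, beta):
    glabels = np.unique(groups)
    ll = np.zeros(y.shape[0])
    for gi, g in enumerate(glabels):
        cols = np.nonzero(groups == g)[0]
        with np.errstate(over="ignore"):
            mu = s[:, cols] * np.exp(beta[:, gi])[:, None]
        ll += _nb_loglik(y[:, cols], mu, phi[:, None]).sum(axis=1)
    return ll


def estimate_dispersion(
    y: np.ndarray,
    s: np.ndarray,
    groups: np.ndarray,
    abundance: np.ndarray,
    grid: Optional[np.ndarray] = None,
    n_bins: int = 10,
    prior_df: float = 160.0,
) -> dict[str, np.ndarray]:
    """Trended NB dispersions with empirical-Bayes shrinkage.

    Per-window dispersions are profiled on a log-spaced grid using the
    Cox-Reid adjusted likelihood. The abundance trend maximises the summed
    adjusted profile likelihood within ``n_bins`` abundance-quantile bins
    (linearly interpolated on log-dispersion between bin centres); window
    values are then shrunk toward the trend with weight prior_df vs the
    residual df.
    """
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-3), np.log(5.0), 25))
    nw, ns = y.shape
    n_groups = len(np.unique(groups))
    resid_df = max(ns - n_groups, 1)
    prof = np.empty((len(grid), nw))
    for i, phi0 in enumerate(grid):
        phi = np.full(nw, phi0)
        beta, info = _fit_group_means(y, s, phi, groups)
        ll = _loglik_groups(y, s, phi, groups, beta)
        with np.errstate(divide="ignore"):
            adj = 0.5 * np.where(info > 0, np.log(np.maximum(info, 1e-300)), 0.0).sum(axis=1)
        prof[i] = ll - adj
    mle = grid[np.argmax(prof, axis=0)]
    log_grid = np.log(grid)

    def _argmax_interp(ll):
        # parabolic refinement of the profile maximum between grid points
        i = int(np.argmax(ll))
        if 0 < i < len(ll) - 1:
            denom = ll[i - 1] - 2 * ll[i] + ll[i + 1]
            if denom < -1e-12:
                shift = 0.5 * (ll[i - 1] - ll[i + 1]) / denom
                shift = float(np.clip(shift, -1.0, 1.0))
                return log_grid[i] + shift * (log_grid[i + 1] - log_grid[i])
        return log_grid[i]

    # trend: common dispersion per abundance bin via summed adjusted likelihood
    n_bins = max(1, min(n_bins, nw // 50)) if nw >= 100 else 1
    qs = np.quantile(abundance, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(qs[1:-1], abundance, side="right"), 0, n_bins - 1)
    centers, log_common = [], []
    for b in range(n_bins):
        inb = bin_idx == b
        if not inb.any():
            continue
        centers.append(float(np.median(abundance[inb])))
        log_common.append(_argmax_interp(prof[:, inb].sum(axis=1)))
    if len(centers) > 1:
        order = np.argsort(centers)
        trend = np.exp(np.interp(abundance, np.array(centers)[order],
                                 np.array(log_common)[order]))
    else:
        trend = np.full(nw, np.exp(log_common[0]))
    shrunk = np.exp(
        (prior_df * np.log(trend) + resid_df * np.log(mle)) / (prior_df + resid_df)
    )
    return {"window": mle, "trend": trend, "shrunk": shrunk}


CHI2_1_MEDIAN = 0.45493642311957283  # median of the chi-square(1) law


def test_windows(
    matrix: WindowCountMatrix,
    offsets: Optional[np.ndarray],
    design: Mapping[str, str] | Sequence[str],
    contrast: tuple[str, str],
    dispersion: Optional[np.ndarray] = None,
    prior_df: float = 160.0,
    gc_calibration: bool = True,
    calibration_mask: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-window NB likelihood-ratio tests for ``condition vs reference``.

    ``design`` maps each library to its condition (or is a label sequence in
    sample order). Dispersions are estimated across *all* conditions with
    replicates (so a single-replicate condition borrows strength; a warning
    is logged), then the contrast pair is tested with a 1-df LRT. Windows
    with zero counts in every contrast library get p = 1, log2fc = 0.

    Returns a DataFrame with chrom/start/end, log2fc, abundance, dispersion
    and p_value.
    """
    if isinstance(design, Mapping):
        labels = np.array([design[s] for s in matrix.samples])
    else:
        labels = np.asarray(list(design))
        if len(labels) != len(matrix.samples):
            raise ValueError("design length does not match samples")
    cond, ref = contrast
    for c in contrast:
        if c not in labels:
            raise ValueError(f"contrast condition {c!r} not in design")
    y = matrix.counts.astype(np.int64)
    nw = matrix.n_windows
    if offsets is None:
        offsets = np.zeros_like(y, dtype=float)
    s = (matrix.library_sizes + 1.0)[None, :] * np.exp(LOG2 * offsets) / 1e6
    # scale to CPM units so group means are log-CPM-ish; cancels in the LRT
    _, counts_per = np.unique(labels, return_counts=True)
    if (counts_per < 2).any():
        logger.warning(
            "condition(s) with a single replicate; dispersion is shared from "
            "replicated conditions across the contrast"
        )
    codes = pd.factorize(labels)[0]
    abundance = matrix.abundance()
    if dispersion is None:
        disp = estimate_dispersion(y, s, codes, abundance, prior_df=prior_df)
        phi = disp["shrunk"]
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (nw,)).copy()
    phi = np.maximum(phi, 1e-6)
    pair = np.isin(labels, [cond, ref])
    yp, sp = y[:, pair], s[:, pair]
    lab = labels[pair]
    g_full = (lab == cond).astype(int)  # 0 = reference, 1 = condition
    beta_full, _ = _fit_group_means(yp, sp, phi, g_full)
    ll_full = _loglik_groups(yp, sp, phi, g_full, beta_full)
    g_null = np.zeros(len(lab), dtype=int)
    beta_null, _ = _fit_group_means(yp, sp, phi, g_null)
    ll_null = _loglik_groups(yp, sp, phi, g_null, beta_null)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    gc_lambda = 1.0
    if gc_calibration:
        # genomic-control correction for the finite-sample inflation of the
        # chi-square reference: scale the statistic by its median over
        # (presumed-null) calibration windows. Only inflation is corrected.
        sel = yp.sum(axis=1) > 0
        if calibration_mask is not None:
            sel &= np.asarray(calibration_mask, dtype=bool)
        if sel.sum() >= 200:
            gc_lambda = max(float(np.median(lrt[sel])) / CHI2_1_MEDIAN, 1.0)
    p = stats.chi2.sf(lrt / gc_lambda, df=1)
    with np.errstate(invalid="ignore"):
        log2fc = (beta_full[:, 1] - beta_full[:, 0]) / LOG2
    allzero = yp.sum(axis=1) == 0
    onezero = ~np.isfinite(log2fc)
    if onezero.any():
        # one group all-zero: report a prior-guarded fold change
        cpm = matrix.log2_cpm()[:, pair]
        lfc_guard = cpm[:, g_full == 1].mean(axis=1) - cpm[:, g_full == 0].mean(axis=1)
        log2fc[onezero] = lfc_guard[onezero]
    p[allzero] = 1.0
    log2fc[allzero] = 0.0
    out = matrix.windows.copy()
    out["log2fc"] = log2fc
    out["abundance"] = abundance
    out["dispersion"] = phi
    out["p_value"] = p
    out.attrs["gc_lambda"] = gc_lambda
    return out


# ---------------------------------------------------------------------------
# Simes combination, BH, promoter calls


def simes_pvalue(pvalues: np.ndarray) -> float:
    """Simes combined p: min over sorted p(i) of m*p(i)/i, capped at 1."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = len(p)
    if m == 0:
        raise ValueError("no p-values to combine")
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def simes_combine(
    window_results: pd.DataFrame,
    promoters: TssAnnotation,
    radius: int = 1000,
) -> pd.DataFrame:
    """Combine window p-values over each promoter (TSS +- radius) with Simes.

    Promoters with no overlapping tested window are absent from the output.
    The promoter direction is the sign of the log2fc at its smallest-p
    window; the reported promoter log2fc is the abundance-weighted mean over
    its windows (a stabler effect size than the extreme window).
    """
    prom = promoters.promoters(radius)
    rows = []
    for chrom, psub in prom.groupby("chrom", sort=False):
        wsub = window_results[window_results["chrom"] == chrom]
        if len(wsub) == 0:
            continue
        wstart = wsub["start"].to_numpy()
        wend = wsub["end"].to_numpy()
        order = np.argsort(wstart)
        wstart, wend = wstart[order], wend[order]
        widx = wsub.index.to_numpy()[order]
        max_w = int((wend - wstart).max())
        for _, pr in psub.iterrows():
            lo = np.searchsorted(wstart, pr["start"] - max_w, side="left")
            hi = np.searchsorted(wstart, pr["end"], side="left")
            cand = np.arange(lo, hi)
            cand = cand[(wend[cand] > pr["start"]) & (wstart[cand] < pr["end"])]
            if len(cand) == 0:
                continue
            sub = window_results.loc[widx[cand]]
            pv = sub["p_value"].to_numpy()
            simes = simes_pvalue(pv)
            best = sub.iloc[int(np.argmin(pv))]
            weights = 2.0 ** sub["abundance"].to_numpy()
            lfc = float(np.average(sub["log2fc"].to_numpy(), weights=weights))
            rows.append(
                (pr["gene_id"], pr["chrom"], int(pr["start"]), int(pr["end"]),
                 len(cand), simes, float(np.sign(best["log2fc"])), lfc,
                 float(np.mean(sub["abundance"])))
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "n_windows", "simes_p",
                 "direction", "log2fc", "abundance"],
    )
    return out


def call_differential(promoter_results: pd.DataFrame, alpha: float = 0.2) -> pd.DataFrame:
    """Attach BH FDR and the strict ``fdr < alpha`` differential flag."""
    out = promoter_results.copy()
    if len(out) == 0:
        out["fdr"] = pd.Series(dtype=float)
        out["is_differential"] = pd.Series(dtype=bool)
        return out
    out["fdr"] = bh_adjust(out["simes_p"].to_numpy())
    out["is_differential"] = out["fdr"] < alpha
    return out


# ---------------------------------------------------------------------------
# Model / Results objects


class DifferentialEnrichment:
    """NB differential-enrichment model over filtered windows.

    Parameters
    ----------
    matrix : WindowCountMatrix
        Counts restricted to enrichment-filtered windows.
    design : mapping or sequence
        Condition label per library.
    promoters : TssAnnotation, optional
        Promoter universe. Enables promoter-level combination on the results
        and the normalization-refinement loop during fitting.
    span : float
        Loess span for MA normalization (0.3 by default).
    prior_df : float
        Strength of dispersion shrinkage toward the abundance trend.

    Notes
    -----
    When differential enrichment is widespread and directionally unbalanced,
    strongly shifted windows migrate to the top of the abundance range and
    can locally dominate the loess fit, so part of the true signal is
    absorbed into the offsets and null windows acquire an opposite-direction
    shift. ``fit`` therefore refines the normalization: windows overlapping
    promoters currently called differential (FDR < alpha) are excluded from
    the loess fit and the model is re-tested, repeating until the called set
    is stable (a handful of iterations). Under a true null the first pass
    calls nothing and refinement is a no-op.
    """

    def __init__(
        self,
        matrix: WindowCountMatrix,
        design: Mapping[str, str] | Sequence[str],
        promoters: Optional[TssAnnotation] = None,
        span: float = 0.3,
        prior_df: float = 160.0,
        normalize: bool = True,
        radius: int = 1000,
    ):
        self.matrix = matrix
        if isinstance(design, Mapping):
            self.design = {s: design[s] for s in matrix.samples}
        else:
            if len(design) != len(matrix.samples):
                raise ValueError("design length does not match samples")
            self.design = dict(zip(matrix.samples, design))
        self.promoters = promoters
        self.span = span
        self.prior_df = prior_df
        self.normalize = normalize
        self.radius = radius

    @classmethod
    def from_matrix(cls, matrix, design, **kwargs) -> "DifferentialEnrichment":
        return cls(matrix, design, **kwargs)

    def drop_samples(self, names: Sequence[str]) -> "DifferentialEnrichment":
        """Explicit outlier removal: a new model without the named libraries."""
        keep = [s for s in self.matrix.samples if s not in set(names)]
        logger.info("dropping sample(s) %s; refit required", ", ".join(names))
        return DifferentialEnrichment(
            self.matrix.subset_samples(keep),
            {s: self.design[s] for s in keep},
            promoters=self.promoters, span=self.span, prior_df=self.prior_df,
            normalize=self.normalize, radius=self.radius,
        )

    def _windows_in_promoters(self, gene_ids) -> np.ndarray:
        """Mask of windows overlapping any of the given promoters."""
        prom = self.promoters.promoters(self.radius)
        prom = prom[prom["gene_id"].isin(set(gene_ids))]
        mask = np.zeros(self.matrix.n_windows, bool)
        for chrom, sub in prom.groupby("chrom", sort=False):
            wsel = (self.matrix.windows["chrom"] == chrom).to_numpy()
            ws = self.matrix.windows.loc[wsel, "start"].to_numpy()
            we = self.matrix.windows.loc[wsel, "end"].to_numpy()
            hit = np.zeros(len(ws), bool)
            for _, p in sub.iterrows():
                hit |= (we > p["start"]) & (ws < p["end"])
            mask[np.nonzero(wsel)[0]] = hit
        return mask

    def fit(
        self,
        contrast: tuple[str, str],
        alpha: float = 0.2,
        top_k: int = 500,
        outlier_c: float = 2.0,
        refine_normalization: bool = True,
        max_refine_iterations: int = 5,
    ) -> "DifferentialEnrichmentResults":
        offsets = loess_normalize(self.matrix, span=self.span) if self.normalize else None
        mds = mds_qc(self.matrix, offsets, top_k=top_k, outlier_c=outlier_c)
        # the genomic-control median calibration presumes technical trends
        # have been removed; an unnormalized fit would launder its bias
        # through the correction, so it only applies when normalizing
        table = test_windows(
            self.matrix, offsets, self.design, contrast, prior_df=self.prior_df,
            gc_calibration=self.normalize,
        )
        n_iter = 0
        excluded: set = set()
        if self.normalize and refine_normalization and self.promoters is not None:
            for n_iter in range(1, max_refine_iterations + 1):
                combined = call_differential(
                    simes_combine(table, self.promoters, self.radius), alpha
                )
                called = set(combined.loc[combined["is_differential"], "gene_id"])
                if called == excluded:
                    break
                excluded = called
                if not excluded:
                    break
                fit_mask = ~self._windows_in_promoters(excluded)
                if fit_mask.sum() < max(200, 0.2 * self.matrix.n_windows):
                    logger.warning(
                        "normalization refinement would exclude almost all "
                        "windows; keeping previous offsets"
                    )
                    break
                offsets = loess_normalize(self.matrix, span=self.span, subset=fit_mask)
                table = test_windows(
                    self.matrix, offsets, self.design, contrast,
                    prior_df=self.prior_df, calibration_mask=fit_mask,
                )
            if excluded:
                logger.info(
                    "normalization refined over %d iteration(s); %d promoters "
                    "excluded from the trend fit", n_iter, len(excluded),
                )
        return DifferentialEnrichmentResults(
            self, contrast, offsets, mds, table,
            alpha=alpha, refine_iterations=n_iter,
        )


class DifferentialEnrichmentResults:
    """Fitted window-level results plus promoter combination and plots."""

    def __init__(self, model, contrast, offsets, mds, window_results,
                 alpha: float = 0.2, refine_iterations: int = 0):
        self.model = model
        self.contrast = contrast
        self.offsets = offsets
        self.mds = mds
        self.window_results = window_results
        self.alpha = alpha
        self.refine_iterations = refine_iterations

    def combine_promoters(
        self,
        promoters: Optional[TssAnnotation] = None,
        radius: Optional[int] = None,
        alpha: Optional[float] = None,
    ) -> pd.DataFrame:
        promoters = promoters if promoters is not None else self.model.promoters
        if promoters is None:
            raise ValueError("no promoter annotation supplied")
        radius = radius if radius is not None else self.model.radius
        alpha = alpha if alpha is not None else self.alpha
        combined = simes_combine(self.window_results, promoters, radius)
        return call_differential(combined, alpha)

    def summary(self) -> str:
        wr = self.window_results
        cond, ref = self.contrast
        lines = [
            "Differential window enrichment (NB LRT)",
            "=" * 42,
            f"contrast:        {cond} vs {ref}",
            f"windows tested:  {len(wr)}",
            f"samples:         {', '.join(self.model.matrix.samples)}",
            f"median dispersion: {np.median(wr['dispersion']):.4f}",
            f"windows p<0.05:  {(wr['p_value'] < 0.05).sum()}",
            f"MDS outliers:    {', '.join(self.mds.outliers) or 'none'}",
        ]
        return "\n".join(lines)

    def plot_ma(self, library: Optional[str] = None, ax=None):
        """MA scatter for one library against the pseudo-reference."""
        import matplotlib.pyplot as plt

        library = library or self.model.matrix.samples[0]
        ma = ma_values(self.model.matrix, library)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(ma["A"], ma["M"], s=2, alpha=0.3)
        ax.axhline(0, color="red", lw=0.8)
        ax.set_xlabel("A (average log2-CPM)")
        ax.set_ylabel(f"M ({library} vs reference)")
        return ax

    def plot_mds(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.mds.coordinates
        ax.scatter(xy[:, 0], xy[:, 1])
        for name, (x, y) in zip(self.mds.samples, xy):
            ax.annotate(name, (x, y), fontsize=8)
        ax.set_xlabel("leading log2FC dim 1")
        ax.set_ylabel("leading log2FC dim 2")
        return ax
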