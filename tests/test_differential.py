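"""MA/loess normalization, MDS QC, NB window tests, Simes and BH."""
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chipdiff as cd
from chipdiff.differential import (
    DifferentialEnrichment,
    bh_adjust,
    call_differential,
    loess_normalize,
    ma_values,
    mds_qc,
    simes_combine,
    simes_pvalue,
)
from chipdiff.differential import test_windows as fit_window_tests
from chipdiff.windows import WindowCountMatrix


def _matrix(counts, lib_sizes=None, samples=None):
    counts = np.asarray(counts)
    n, k = counts.shape
    windows = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 150,
                            "end": np.arange(n) * 150 + 150})
    samples = samples or [f"s{i}" for i in range(k)]
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return WindowCountMatrix(windows, counts, samples, np.asarray(lib_sizes, float))


class TestMaValues:
    def test_identical_libraries_have_zero_m(self):
        mat = _matrix(np.tile([[10], [40], [5]], (1, 3)), [100, 100, 100])
        ma = ma_values(mat, "s0")
        np.testing.assert_allclose(ma["M"], 0.0, atol=1e-12)

    def test_doubling_counts_shifts_m_by_one_against_fixed_reference(self):
        base = np.tile([[10], [40], [5]], (1, 3))
        mat = _matrix(base, [100, 100, 100])
        ref = mat.log2_cpm().mean(axis=1)
        doubled = base.copy()
        doubled[:, 0] = 2 * base[:, 0] - 0  # counts doubled, sizes fixed
        mat2 = _matrix(doubled, [100, 100, 100])
        ma = ma_values(mat2, "s0", reference=ref)
        # prior count 0.5 leaves a small deviation from exactly +1
        np.testing.assert_allclose(ma["M"], 1.0, atol=0.1)

    def test_three_window_toy_matches_formula(self):
        counts = np.array([[4, 9], [0, 2], [20, 20]])
        mat = _matrix(counts, [50, 60])
        log2cpm = np.log2((counts + 0.5) / (np.array([50, 60]) + 1.0) * 1e6)
        ref = log2cpm.mean(axis=1)
        ma = ma_values(mat, "s1")
        np.testing.assert_allclose(ma["M"], log2cpm[:, 1] - ref, atol=1e-12)
        np.testing.assert_allclose(ma["A"], ref, atol=1e-12)


class TestLoess:
    def test_identical_libraries_give_zero_offsets(self):
        rng = np.random.default_rng(0)
        col = rng.integers(5, 500, 400)[:, None]
        mat = _matrix(np.tile(col, (1, 2)), [1e4, 1e4])
        off = loess_normalize(mat, span=0.5)
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_planted_linear_bias_recovered(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(np.log(50), 1.0, 3000)
        y0 = rng.poisson(mu)
        y1 = rng.poisson(mu * 2.0**0.5)  # constant +0.5 log2 bias
        mat = _matrix(np.column_stack([y0, y1]), [mu.sum(), mu.sum() * 2**0.5])
        off = loess_normalize(mat, span=0.4)
        rel = off[:, 1] - off[:, 0]
        a = mat.abundance()
        interior = (a > np.quantile(a, 0.1)) & (a < np.quantile(a, 0.9))
        # library sizes already absorb the mean shift; the fitted relative
        # offset curve must be flat (within 0.05) over interior abundances
        assert np.abs(rel[interior]).mean() < 0.05

    def test_planted_monotone_bias_flattened(self):
        cfg = cd.SimulationConfig(seed=31, n_promoters=800,
                                  n_differential_tg=0, n_differential_nontg=0)
        mat, truth, _ = cd.simulate_window_counts(cfg)
        off = loess_normalize(mat)
        lcpm = mat.log2_cpm()
        a = lcpm.mean(axis=1)
        resid = (lcpm - a[:, None]) - off
        deciles = np.quantile(a, np.linspace(0, 1, 11))
        for j in range(lcpm.shape[1]):
            for d in range(10):
                sel = (a >= deciles[d]) & (a <= deciles[d + 1])
                assert abs(resid[sel, j].mean()) < 0.1

    def test_too_few_windows_suggests_larger_span(self):
        mat = _matrix(np.ones((20, 2), dtype=int), [100, 100])
        with pytest.raises(ValueError, match="span"):
            loess_normalize(mat, span=0.05)


class TestMdsQc:
    def test_duplicated_sample_has_zero_distance(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 300, 600)
        counts = np.column_stack([col, col, rng.integers(1, 300, 600)])
        mat = _matrix(counts)
        res = mds_qc(mat, top_k=100)
        assert res.distances[0, 1] == 0.0
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-8)

    def test_distance_matrix_matches_brute_force_top_k_rms(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 400, size=(500, 4))
        mat = _matrix(counts)
        res = mds_qc(mat, top_k=50)
        expr = mat.log2_cpm()
        for u in range(4):
            for v in range(4):
                if u == v:
                    continue
                diffs = np.sort(np.abs(expr[:, u] - expr[:, v]))[::-1][:50]
                assert res.distances[u, v] == pytest.approx(
                    np.sqrt(np.mean(diffs**2)), abs=1e-12)

    def test_planted_outlier_replicate_flagged(self):
        cfg = cd.SimulationConfig(seed=1, n_differential_tg=0,
                                  n_differential_nontg=0,
                                  outlier_replicate="k4_TG_A")
        mat, truth, _ = cd.simulate_window_counts(cfg)
        off = loess_normalize(mat)
        res = mds_qc(mat, off, top_k=500, outlier_c=2.0)
        assert res.outliers == ["k4_TG_A"]


class TestTestWindows:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        mu = rng.lognormal(np.log(30), 0.7, 4000)
        phi = 0.05
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu[:, None]),
                                  size=(4000, 6))
        mat = _matrix(y, [3e4] * 6)
        res = fit_window_tests(mat, None, ["a"] * 3 + ["b"] * 3, ("b", "a"))
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_log2fc_recovered(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(60), 0.5, 2000)
        phi = 0.05
        y_a = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu[:, None]), (2000, 3))
        y_b = rng.negative_binomial(1 / phi, 1 / (1 + phi * 4 * mu[:, None]), (2000, 3))
        mat = _matrix(np.hstack([y_a, y_b]), [1e5] * 6)
        res = fit_window_tests(mat, None, ["a"] * 3 + ["b"] * 3, ("b", "a"))
        assert abs(np.median(res["log2fc"]) - 2.0) < 0.25

    def test_all_zero_window_gets_p_one(self):
        y = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        mat = _matrix(y, [100] * 4)
        res = fit_window_tests(mat, None, ["a", "a", "b", "b"], ("b", "a"))
        assert res["p_value"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_single_replicate_condition_borrows_dispersion(self, caplog):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(np.log(40), 0.5, 500)
        phi = 0.05
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu[:, None]), (500, 3))
        mat = _matrix(y, [2e4] * 3)
        import logging

        with caplog.at_level(logging.WARNING):
            res = fit_window_tests(mat, None, ["a", "a", "b"], ("b", "a"))
        assert "single replicate" in caplog.text
        assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()

    def test_agrees_with_edger_reference_on_log2fc(self, tmp_path):
        """Independent cross-check of effect sizes against edgeR's GLM."""
        rng = np.random.default_rng(7)
        mu = rng.lognormal(np.log(50), 0.8, 300)
        phi = 0.1
        lfc = np.where(rng.random(300) < 0.2, rng.normal(0, 1.5, 300), 0.0)
        y_a = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu[:, None]), (300, 3))
        mu_b = mu * 2.0**lfc
        y_b = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu_b[:, None]), (300, 3))
        counts = np.hstack([y_a, y_b])
        mat = _matrix(counts, counts.sum(axis=0))
        res = fit_window_tests(mat, None, ["a"] * 3 + ["b"] * 3, ("b", "a"))
        cpath = tmp_path / "counts.tsv"
        pd.DataFrame(counts).to_csv(cpath, sep="\t", index=False)
        rscript = textwrap.dedent("""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.delim('%s'))
            group <- factor(c('a','a','a','b','b','b'))
            d <- DGEList(y, group=group)
            design <- model.matrix(~group)
            d <- estimateDisp(d, design)
            fit <- glmFit(d, design)
            lrt <- glmLRT(fit)
            write.table(lrt$table, '%s', sep='\\t', quote=FALSE)
        """ % (cpath, tmp_path / "edger.tsv"))
        subprocess.run(["Rscript", "-e", rscript], check=True,
                       capture_output=True)
        edger = pd.read_csv(tmp_path / "edger.tsv", sep="\t")
        r = np.corrcoef(res["log2fc"].to_numpy(), edger["logFC"].to_numpy())[0, 1]
        assert r > 0.95
        assert np.median(np.abs(res["log2fc"].to_numpy() - edger["logFC"].to_numpy())) < 0.2


class TestSimesAndBh:
    def test_simes_example(self):
        assert simes_pvalue([0.01, 0.02, 0.9]) == pytest.approx(0.03)

    def test_simes_single_and_degenerate(self):
        assert simes_pvalue([0.05]) == 0.05
        assert simes_pvalue([1.0, 1.0, 1.0]) == 1.0

    def test_simes_bounds_and_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            m = rng.integers(1, 12)
            p = rng.random(m)
            s = simes_pvalue(p)
            brute = min(1.0, min(len(p) * pv / (i + 1)
                                 for i, pv in enumerate(sorted(p))))
            assert s == pytest.approx(brute, abs=1e-12)
            assert min(p) <= s <= min(1.0, len(p) * min(p))

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_value_and_monotonicity(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)
        rng = np.random.default_rng(9)
        p = rng.random(200)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            m = len(p)
            brute = np.empty(m)
            for i, pv in enumerate(p):
                rank = np.sum(np.sort(p) <= pv)
                brute[i] = min(
                    min(m * q / (np.searchsorted(np.sort(p), q, "right"))
                        for q in np.sort(p)[rank - 1 :]),
                    1.0,
                )
            np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)


class TestPromoterCombination:
    def _windows(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2fc",
                                           "abundance", "dispersion", "p_value"])

    def _tss(self, positions):
        return cd.TssAnnotation(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(positions))],
            "chrom": "chr1", "tss": positions, "strand": "+"}))

    def test_simes_over_overlapping_windows(self):
        wr = self._windows([
            ("chr1", 4800, 4950, 1.0, 5.0, 0.05, 0.01),
            ("chr1", 4950, 5100, 2.0, 5.0, 0.05, 0.02),
            ("chr1", 5100, 5250, -1.0, 5.0, 0.05, 0.9),
            ("chr1", 9000, 9150, 1.0, 5.0, 0.05, 0.5),  # outside promoter
        ])
        out = simes_combine(wr, self._tss([5000]), radius=1000)
        assert len(out) == 1
        assert out["n_windows"].iloc[0] == 3
        assert out["simes_p"].iloc[0] == pytest.approx(0.03)
        assert out["direction"].iloc[0] == 1.0  # sign at the smallest p

    def test_promoter_without_windows_absent(self):
        wr = self._windows([("chr1", 100, 250, 1.0, 5.0, 0.05, 0.5)])
        out = simes_combine(wr, self._tss([50_000]), radius=1000)
        assert len(out) == 0

    def test_fdr_threshold_is_strict(self):
        prom = pd.DataFrame({
            "gene_id": ["a", "b"], "chrom": "chr1", "start": [0, 5000],
            "end": [2000, 7000], "n_windows": [1, 1],
            "simes_p": [0.1, 0.2], "direction": [1.0, -1.0],
            "log2fc": [1.0, -1.0], "abundance": [5.0, 5.0]})
        out = call_differential(prom, alpha=0.2)
        # BH: fdr = {0.2, 0.2}; strict inequality calls neither
        assert not out["is_differential"].any()
        out2 = call_differential(prom.assign(simes_p=[0.0999, 0.9]), alpha=0.2)
        assert out2["is_differential"].tolist() == [True, False]

    def test_empty_input_gives_empty_output(self):
        out = call_differential(pd.DataFrame(columns=[
            "gene_id", "chrom", "start", "end", "n_windows", "simes_p",
            "direction", "log2fc", "abundance"]))
        assert len(out) == 0 and "is_differential" in out


class TestModelObject:
    def test_fit_returns_results_with_summary(self):
        cfg = cd.SimulationConfig(seed=41, n_promoters=400,
                                  n_differential_tg=50, n_differential_nontg=10)
        mat, truth, _ = cd.simulate_window_counts(cfg)
        tss = cd.simulate_annotation(cfg, truth)[1]
        names = [n for n in mat.samples if n.split("_")[1] in ("CRwt", "TG")]
        model = DifferentialEnrichment(
            mat.subset_samples(names),
            {n: n.split("_")[1] for n in names}, promoters=tss)
        res = model.fit(("TG", "CRwt"))
        text = res.summary()
        assert "TG vs CRwt" in text and "windows tested" in text
        prom = res.combine_promoters()
        assert {"simes_p", "fdr", "is_differential"} <= set(prom.columns)

    def test_drop_samples_requires_refit(self):
        cfg = cd.SimulationConfig(seed=42, n_promoters=300,
                                  n_differential_tg=0, n_differential_nontg=0)
        mat, truth, _ = cd.simulate_window_counts(cfg)
        model = DifferentialEnrichment(
            mat, {n: n.split("_")[1] for n in mat.samples})
        smaller = model.drop_samples(["k4_TG_A"])
        assert "k4_TG_A" not in smaller.matrix.samples
        assert len(smaller.matrix.samples) == len(mat.samples) - 1
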