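"""EM allele frequencies, SNP calling and the paralog filter."""

import numpy as np
import pandas as pd
import pytest

from glpopgen.filters import (
    SiteFilterConfig,
    apply_filters,
    call_snps,
    estimate_maf_em,
    estimate_maf_em_single,
    loglik_at_freq,
    paralog_test,
)
from glpopgen.glcore import GLMatrix

from conftest import degenerate_gls


def _matrix(genotypes: np.ndarray) -> GLMatrix:
    S, N = genotypes.shape
    sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, S + 1) * 100,
                          "major": "A", "minor": "C"})
    inds = pd.DataFrame({"id": [f"i{k}" for k in range(N)], "pop": "x"})
    return GLMatrix(sites, inds, degenerate_gls(genotypes))


class TestMafEM:
    def test_all_hom_major_gives_zero(self):
        f = estimate_maf_em_single(degenerate_gls(np.zeros((1, 6), int))[0])
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_known_genotypes_reduce_to_counting(self):
        # one het + one hom-major: 1 minor allele among 4.
        f = estimate_maf_em_single(degenerate_gls(np.array([[1, 0]]))[0])
        assert f == pytest.approx(0.25, abs=1e-10)

    def test_recovery_at_depth_twenty(self):
        from glpopgen.glcore import gl_from_counts
        rng = np.random.default_rng(8)
        S, N, f_true = 100, 50, 0.3
        g = rng.binomial(2, f_true, size=(S, N))
        d = rng.poisson(20, size=(S, N))
        minor_reads = rng.binomial(d, g / 2.0)
        counts = np.zeros((S, N, 4), dtype=int)
        counts[:, :, 0] = d - minor_reads
        counts[:, :, 1] = minor_reads
        gls = gl_from_counts(counts, np.zeros(S, int), np.ones(S, int), 0.01)
        f, _ = estimate_maf_em(gls)
        # At 20x the estimable quantity is the realized sample frequency;
        # the parameter itself carries binomial sampling noise ~0.046 SD.
        f_sample = g.sum(axis=1) / (2 * N)
        assert np.mean(np.abs(f - f_sample)) < 0.02
        assert np.mean(np.abs(f - f_true)) < 0.05

    def test_estimate_is_local_maximum(self):
        rng = np.random.default_rng(4)
        gls = rng.dirichlet(np.ones(3), size=(30, 10))
        f, ll = estimate_maf_em(gls, tol=1e-12, max_iter=5000)
        for df in (0.01, -0.01):
            perturbed = np.clip(f + df, 1e-9, 1 - 1e-9)
            assert np.all(loglik_at_freq(gls, perturbed) <= ll + 1e-9)

    def test_all_missing_column_undefined(self):
        gls = np.full((1, 5, 3), 1 / 3)
        f, _ = estimate_maf_em(gls)
        assert np.isnan(f[0])


class TestCallSnps:
    def test_invariant_site_fails_snp_flag(self):
        gl = _matrix(np.zeros((1, 10), int))
        table = call_snps(gl, SiteFilterConfig(min_total_depth=0))
        assert table["snp_p"].iloc[0] == pytest.approx(1.0)
        assert bool(table["snp_fail"].iloc[0])

    def test_low_depth_fails_default_bounds(self):
        gl = _matrix(np.array([[0, 1, 1, 2]]))
        table = call_snps(gl, SiteFilterConfig(),
                          total_depth=np.array([100]))
        assert bool(table["depth_fail"].iloc[0])

    def test_maf_counting_on_constructed_fixture(self):
        # 10 sites with known genotypes over 10 individuals; 3 sites carry a
        # single minor allele (MAF 0.05 < 0.1), the rest 4 copies (MAF 0.2).
        g = np.zeros((10, 10), int)
        for s in range(7):
            g[s, :4] = 1
        for s in range(7, 10):
            g[s, 0] = 1
        gl = _matrix(g)
        cfg = SiteFilterConfig(maf_min=0.1, min_total_depth=0,
                               snp_p_max=1.0)
        table = call_snps(gl, cfg, run_paralog_test=False)
        assert int(table["pass"].sum()) == 7

    def test_maf_folding_relabels_major_minor(self):
        g = np.full((1, 10), 2)
        g[0, 0] = 1  # minor allele frequency of the labelled major: 1/20
        gl = _matrix(g)
        table = call_snps(gl, SiteFilterConfig(min_total_depth=0),
                          run_paralog_test=False)
        assert table["maf"].iloc[0] == pytest.approx(0.05, abs=1e-9)
        assert table["major"].iloc[0] == "C"
        filtered = apply_filters(
            gl, table.assign(**{"pass": [True]})
        )
        # GL triples flipped to match the relabeled polarization.
        assert filtered.gls[0, 0, 1] == 1.0
        assert filtered.gls[0, 1, 0] == 1.0


class TestParalogTest:
    def test_hwe_site_retained(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, size=(1, 200))
        res = paralog_test(degenerate_gls(g), np.array([g.mean() / 2]))
        assert res["LR"].iloc[0] < 3.84

    def test_all_heterozygous_strongly_excluded(self):
        g = np.ones((1, 20), int)
        res = paralog_test(degenerate_gls(g), np.array([0.5]))
        assert res["F_hat"].iloc[0] == pytest.approx(-1.0, abs=1e-3)
        assert res["LR"].iloc[0] > 3.84 * 3

    def test_null_calibration_bonferroni(self):
        from glpopgen.glcore import gl_from_counts
        rng = np.random.default_rng(12)
        S, N = 2000, 20
        f = rng.uniform(0.1, 0.5, size=S)
        g = rng.binomial(2, f[:, None], size=(S, N))
        d = rng.poisson(20, size=(S, N))
        minor_reads = rng.binomial(d, g / 2.0)
        counts = np.zeros((S, N, 4), dtype=int)
        counts[:, :, 0] = d - minor_reads
        counts[:, :, 1] = minor_reads
        gls = gl_from_counts(counts, np.zeros(S, int), np.ones(S, int), 0.01)
        fhat, _ = estimate_maf_em(gls)
        res = paralog_test(gls, fhat)
        p = res["p"].dropna().to_numpy()
        assert 0.3 < p.mean() < 0.7  # roughly uniform under the null
        n_excluded = (np.minimum(p * len(p), 1.0) < 0.05).sum()
        assert n_excluded / len(p) <= 0.05

    def test_monomorphic_site_skipped(self):
        g = np.zeros((1, 10), int)
        res = paralog_test(degenerate_gls(g), np.array([0.0]))
        assert np.isnan(res["p"].iloc[0])


class TestConfig:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SiteFilterConfig(maf_min=0.6)
        with pytest.raises(ValueError):
            SiteFilterConfig(min_total_depth=10, max_total_depth=5)
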