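"""PCA covariance, admixture EM and AICc model choice."""

import numpy as np
import pandas as pd
import pytest

from glpopgen import structure
from glpopgen.glcore import GLMatrix
from glpopgen.structure import (
    AdmixtureResult,
    admixture_em,
    aicc_select,
    balanced_subsample,
    covariance_pca,
)

from conftest import degenerate_gls


def _matrix(genotypes, pops=None):
    S, N = genotypes.shape
    sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, S + 1) * 10,
                          "major": "A", "minor": "C"})
    if pops is None:
        pops = ["x"] * N
    inds = pd.DataFrame({"id": [f"i{k}" for k in range(N)], "pop": pops})
    return GLMatrix(sites, inds, degenerate_gls(genotypes))


class TestCovariancePCA:
    def test_two_fixed_groups_separate_on_pc1(self):
        S, half = 50, 6
        g = np.zeros((S, 2 * half), int)
        g[:, half:] = 2
        res = covariance_pca(_matrix(g))
        assert res.pct_variance[0] > 99.0
        pc1 = res.eigenvectors[:, 0]
        assert np.ptp(np.sign(pc1[:half])) == 0
        assert np.all(np.sign(pc1[:half]) != np.sign(pc1[half:]))
        # Within-group covariance positive, between-group negative, equal size.
        C = res.cov
        within = C[0, 1]
        between = C[0, half]
        assert within > 0 > between
        assert abs(within) == pytest.approx(abs(between), rel=1e-6)

    def test_duplicated_individual_coincides(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(80, 6))
        g = np.column_stack([g, g[:, 0]])  # duplicate individual 0
        res = covariance_pca(_matrix(g))
        coords = res.coordinates(k=3)
        a = coords.loc[0, ["PC1", "PC2", "PC3"]].to_numpy(float)
        b = coords.loc[6, ["PC1", "PC2", "PC3"]].to_numpy(float)
        assert np.allclose(a, b, atol=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(60, 8))
        gl = _matrix(g)
        res = covariance_pca(gl)
        perm = rng.permutation(8)
        res_p = covariance_pca(gl.subset_individuals(perm))
        assert np.allclose(res.eigenvalues, res_p.eigenvalues, atol=1e-9)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, size=(60, 8))
        gl = _matrix(g)
        res = covariance_pca(gl)
        flipped = gl.gls.copy()
        flipped[::2] = flipped[::2][:, :, ::-1]  # relabel alleles at half the sites
        gl2 = GLMatrix(gl.sites, gl.individuals, flipped)
        res2 = covariance_pca(gl2)
        assert np.allclose(res.cov, res2.cov, atol=1e-9)

    def test_pct_variance_sums_to_100(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, size=(40, 6))
        res = covariance_pca(_matrix(g))
        assert res.pct_variance.sum() == pytest.approx(100.0)


class TestBalancedSubsample:
    def test_downsamples_large_pops_only(self):
        inds = pd.DataFrame(
            {"id": [f"i{k}" for k in range(40)],
             "pop": ["a"] * 25 + ["b"] * 15}
        )
        idx = balanced_subsample(inds, max_per_pop=16, seed=0)
        pops = inds.loc[idx, "pop"]
        assert (pops == "a").sum() == 16
        assert (pops == "b").sum() == 15
        # seeded: reproducible
        assert np.array_equal(idx, balanced_subsample(inds, 16, seed=0))


class TestAdmixture:
    def test_k1_reduces_to_hwe_maf(self, two_pop_deep):
        _, gl, _, _ = two_pop_deep
        from glpopgen.filters import estimate_maf_em, loglik_at_freq

        res = admixture_em(gl, K=1)
        f, _ = estimate_maf_em(gl.gls)
        keep = np.isfinite(f) & (f > 1e-6) & (f < 1 - 1e-6)
        assert np.allclose(res.Q, 1.0)
        assert np.allclose(res.F[:, 0], f[keep], atol=1e-5)
        assert res.loglik == pytest.approx(
            float(loglik_at_freq(gl.gls[keep], f[keep]).sum()), rel=1e-6
        )

    def test_two_population_recovery(self, two_pop_deep):
        cfg, gl, _, _ = two_pop_deep
        res = admixture_em(gl, K=2, seed=5, n_restarts=3, max_iter=500)
        own = []
        labels = gl.individuals["pop"].to_numpy()
        # Each individual's dominant cluster should agree within populations.
        dom = res.Q.argmax(axis=1)
        for pop in ("P1", "P2"):
            sub = dom[labels == pop]
            own.append(max((sub == 0).mean(), (sub == 1).mean()))
        assert min(own) > 0.95
        assert res.Q.sum(axis=1) == pytest.approx(np.ones(len(res.Q)), abs=1e-8)

    def test_loglik_monotone_within_run(self, two_pop_deep):
        _, gl, _, _ = two_pop_deep
        res = admixture_em(gl, K=2, seed=1, n_restarts=1, max_iter=100)
        path = res.loglik_path
        assert np.all(np.diff(path) > -1e-6)

    def test_label_permutation_leaves_loglik_unchanged(self, two_pop_deep):
        _, gl, _, _ = two_pop_deep
        from glpopgen.filters import estimate_maf_em
        from glpopgen.structure import _admixture_loglik

        res = admixture_em(gl, K=2, seed=2, n_restarts=1, max_iter=200)
        f, _ = estimate_maf_em(gl.gls)
        keep = np.isfinite(f) & (f > 1e-6) & (f < 1 - 1e-6)
        gls = gl.gls[keep]
        ll = _admixture_loglik(gls, res.F @ res.Q.T)
        ll_swapped = _admixture_loglik(gls, res.F[:, ::-1] @ res.Q[:, ::-1].T)
        assert ll == pytest.approx(ll_swapped, abs=1e-6)


class TestAICc:
    def _fit(self, ll, K):
        return AdmixtureResult(np.ones((1, K)), np.ones((1, K)), ll, K, 0,
                               True, 1)

    def test_formula_evaluation(self):
        # N=20, S=5, K=1: p = 5 params, n = 100 obs, lnL = -100.
        df = aicc_select({1: self._fit(-100.0, 1)}, n_individuals=20, n_sites=5)
        assert df["aicc"].iloc[0] == pytest.approx(210 + 60 / 94, abs=1e-4)
        assert not df["best"].any()  # single fit: no selection

    def test_aic_fallback_when_overparameterized(self):
        df = aicc_select(
            {1: self._fit(-10.0, 1), 2: self._fit(-9.0, 2)},
            n_individuals=2, n_sites=2,
        )
        assert df["used_aic"].any()

    def test_equal_loglik_prefers_smaller_k(self):
        df = aicc_select(
            {2: self._fit(-50.0, 2), 3: self._fit(-50.0, 3)},
            n_individuals=50, n_sites=1000,
        )
        assert df.loc[df["best"], "K"].iloc[0] == 2
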