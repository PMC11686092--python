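"""SAF likelihoods, SFS EM, windowed diversity and inbreeding."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from glpopgen.diversity import (
    compare_window_means,
    fold_saf,
    inbreeding_em,
    saf_likelihoods,
    saf_site,
    sfs_em,
    site_stats,
    tajima_constants,
    window_thetas,
)

from conftest import degenerate_gls


def brute_force_saf(gl_column: np.ndarray) -> np.ndarray:
    """Enumeration oracle: P(data | j) over all genotype configurations.

    P(data | j) = sum over (g_1..g_N) with sum g = j of
    prod_i GL_i[g_i] * prod_i C(2, g_i) / C(2N, j).
    """
    N = gl_column.shape[0]
    J = 2 * N + 1
    out = np.zeros(J)
    for config in product(range(3), repeat=N):
        j = sum(config)
        w = 1.0
        for i, g in enumerate(config):
            w *= gl_column[i, g] * comb(2, g)
        out[j] += w
    binom = np.array([comb(2 * N, j) for j in range(J)], dtype=float)
    out = out / binom
    return out / out.max()


class TestSAF:
    def test_single_hom_minor_point_mass(self):
        gl = degenerate_gls(np.array([[2]]))
        unfolded = saf_likelihoods(gl)
        assert np.argmax(unfolded[0]) == 2
        assert unfolded[0, 0] == 0 and unfolded[0, 1] == 0
        folded = saf_site(gl[0])
        # j=2 of 2 chromosomes folds with j=0: monomorphic-in-sample class.
        assert np.argmax(folded) == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            col = rng.dirichlet(np.ones(3), size=4)
            mine = fold_saf(saf_likelihoods(col[None]))[0]
            oracle_unfolded = brute_force_saf(col)
            N = 4
            oracle = np.empty(N + 1)
            for j in range(N):
                oracle[j] = oracle_unfolded[j] + oracle_unfolded[2 * N - j]
            oracle[N] = oracle_unfolded[N]
            oracle /= oracle.max()
            assert np.allclose(mine, oracle, atol=1e-10)

    def test_two_double_hets_match_enumeration(self):
        col = degenerate_gls(np.array([[1, 1]]))[0]
        assert np.allclose(
            saf_likelihoods(col[None])[0],
            brute_force_saf(col),
            atol=1e-12,
        )

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        col = rng.dirichlet(np.ones(3), size=6)
        a = saf_site(col)
        b = saf_site(col[::-1])
        assert np.allclose(a, b, atol=1e-12)


class TestSfsEM:
    def test_degenerate_gls_equal_count_histogram(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.3, size=(300, 10))
        saf = fold_saf(saf_likelihoods(degenerate_gls(g)))
        sfs = sfs_em(saf)
        j = g.sum(axis=1)
        folded_j = np.minimum(j, 20 - j)
        hist = np.bincount(folded_j, minlength=11)
        assert np.allclose(sfs, hist, atol=1e-6)
        assert sfs.sum() == pytest.approx(300.0)

    def test_all_invariant_mass_at_zero(self):
        g = np.zeros((50, 8), int)
        sfs = sfs_em(fold_saf(saf_likelihoods(degenerate_gls(g))))
        assert sfs[0] == pytest.approx(50.0, abs=1e-8)
        assert np.allclose(sfs[1:], 0.0, atol=1e-8)


class TestWindowThetas:
    def _sites(self, n, spacing=10):
        return pd.DataFrame({"chrom": "chr1",
                             "pos": np.arange(1, n + 1) * spacing})

    def test_no_segregating_sites(self):
        g = np.zeros((20, 6), int)
        saf = fold_saf(saf_likelihoods(degenerate_gls(g)))
        sfs = sfs_em(saf)
        win = window_thetas(saf, sfs, self._sites(20), {"chr1": 200},
                            window_size=200, step=200)
        row = win.iloc[0]
        assert row["theta_w"] == pytest.approx(0.0, abs=1e-8)
        assert row["pi"] == pytest.approx(0.0, abs=1e-8)
        assert np.isnan(row["tajima_d"])

    def test_pi_matches_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        N = 8
        g = rng.binomial(2, 0.35, size=(40, N))
        saf = fold_saf(saf_likelihoods(degenerate_gls(g)))
        sfs = sfs_em(saf)
        win = window_thetas(saf, sfs, self._sites(40), {"chr1": 400},
                            window_size=400, step=400)
        # O(n^2) oracle: expand genotypes to 2N haploid alleles; pi is the
        # mean pairwise difference count summed over sites.
        pi_oracle = 0.0
        for s in range(40):
            alleles = np.repeat([0, 1], [2 * N - g[s].sum(), g[s].sum()])
            diffs = sum(
                alleles[i] != alleles[j]
                for i in range(2 * N) for j in range(i + 1, 2 * N)
            )
            pi_oracle += diffs / comb(2 * N, 2)
        assert win["pi"].iloc[0] == pytest.approx(pi_oracle, abs=1e-10)

    def test_tajima_d_matches_textbook_constants(self):
        rng = np.random.default_rng(13)
        N = 10
        g = rng.binomial(2, 0.25, size=(60, N))
        saf = fold_saf(saf_likelihoods(degenerate_gls(g)))
        sfs = sfs_em(saf)
        win = window_thetas(saf, sfs, self._sites(60), {"chr1": 600},
                            window_size=600, step=600)
        n = 2 * N
        S = int((g.sum(axis=1) % (2 * N) != 0).sum())
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        pi = win["pi"].iloc[0]
        d_oracle = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert win["tajima_d"].iloc[0] == pytest.approx(d_oracle, abs=1e-10)

    def test_all_singletons_give_negative_d(self):
        N = 10
        g = np.zeros((50, N), int)
        g[:, 0] = 1  # every site a singleton
        saf = fold_saf(saf_likelihoods(degenerate_gls(g)))
        sfs = sfs_em(saf)
        win = window_thetas(saf, sfs, self._sites(50), {"chr1": 500},
                            window_size=500, step=500)
        assert win["tajima_d"].iloc[0] < 0

    def test_sliding_windows_tile_with_final_partial(self):
        g = np.zeros((30, 4), int)
        g[:, 0] = 1
        saf = fold_saf(saf_likelihoods(degenerate_gls(g)))
        sfs = sfs_em(saf)
        win = window_thetas(saf, sfs, self._sites(30), {"chr1": 298},
                            window_size=100, step=50)
        # Anchored at 1, advancing by 50; the window reaching the chromosome
        # end is clipped there, kept, and flagged partial.
        assert list(win["start"]) == [1, 51, 101, 151, 201]
        assert win["end"].iloc[-1] == 298
        assert bool(win["partial"].iloc[-1])
        assert (win["end"].iloc[:-1] - win["start"].iloc[:-1] + 1 == 100).all()


class TestInbreeding:
    def test_fully_homozygous_hits_upper_bound(self):
        rng = np.random.default_rng(15)
        g = 2 * rng.integers(0, 2, size=(200, 1))
        res = inbreeding_em(degenerate_gls(g), np.full(200, 0.5))
        assert res["F_hat"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_hwe_sample_near_zero(self):
        from glpopgen.glcore import gl_from_counts
        rng = np.random.default_rng(16)
        S, N = 1500, 30
        f = rng.uniform(0.1, 0.5, size=S)
        g = rng.binomial(2, f[:, None], size=(S, N))
        d = rng.poisson(20, size=(S, N))
        minor = rng.binomial(d, g / 2.0)
        counts = np.zeros((S, N, 4), int)
        counts[:, :, 0] = d - minor
        counts[:, :, 1] = minor
        gls = gl_from_counts(counts, np.zeros(S, int), np.ones(S, int), 0.01)
        res = inbreeding_em(gls, f)
        assert abs(res["F_hat"].mean()) < 0.02

    def test_all_heterozygous_floors_at_zero(self):
        g = np.ones((100, 1), int)
        res = inbreeding_em(degenerate_gls(g), np.full(100, 0.5))
        assert res["F_hat"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_low_confidence_flag(self):
        g = np.ones((10, 1), int)
        res = inbreeding_em(degenerate_gls(g), np.full(10, 0.5))
        assert bool(res["low_confidence"].iloc[0])


class TestCompareWindowMeans:
    def test_identical_groups(self):
        r = compare_window_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["mean_diff"] == 0.0
        assert r["p"] == pytest.approx(1.0)

    def test_textbook_t(self):
        r = compare_window_means([1, 2, 3], [4, 5, 6])
        assert r["t"] == pytest.approx(-3.674, abs=1e-3)
        assert r["p"] == pytest.approx(0.0214, abs=1e-3)

    def test_swap_symmetry(self):
        r1 = compare_window_means([1, 2, 3], [4, 5, 9])
        r2 = compare_window_means([4, 5, 9], [1, 2, 3])
        assert r1["mean_diff"] == pytest.approx(-r2["mean_diff"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            compare_window_means([1.0], [2.0, 3.0])
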