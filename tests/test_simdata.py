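"""Synthetic-data generator: statistical structure and determinism."""

import numpy as np
import pytest

from glpopgen import simdata
from glpopgen.simdata import (
    SimConfig,
    simulate_allele_frequencies,
    simulate_mito_alignment,
    simulate_reads,
)


def _cfg(**kw) -> SimConfig:
    base = dict(
        n_pops=2, pop_sizes=(10, 10), pop_names=("P1", "P2"),
        n_sites=200, chrom_lengths={"chr1": 200_000},
        fst_target=(0.05, 0.05), depth_lambda=2.0, error_rate=0.01,
        sweep_region=None, paralog_fraction=0.0, mito_length=300,
        mito_mutations=5.0, seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestAlleleFrequencies:
    def test_zero_fst_copies_ancestral_exactly(self):
        cfg = _cfg(fst_target=(0.0, 0.0))
        freqs, truth = simulate_allele_frequencies(cfg)
        anc = truth.sites["ancestral_freq"].to_numpy()
        assert np.array_equal(freqs[:, 0], anc)
        assert np.array_equal(freqs[:, 1], anc)

    def test_balding_nichols_variance_matches_beta_moment(self):
        # Var(pop freq) = p(1-p) F; at p = 0.5, F = 0.1 that is 0.025.
        rng = np.random.default_rng(42)
        p = np.full(10_000, 0.5)
        draws = simdata._balding_nichols(p, 0.1, rng)
        assert np.var(draws) == pytest.approx(0.025, rel=0.1)

    def test_sweep_offset_forces_frequency(self):
        cfg = _cfg(
            fst_target=(0.0, 0.0),
            ancestral_maf_range=(0.1, 0.100001),
            sweep_region=("chr1", 50_000, 150_000, (0.0, 0.8)),
            sweep_n_snps=10,
        )
        freqs, truth = simulate_allele_frequencies(cfg)
        sw = truth.sites["is_sweep"].to_numpy()
        assert sw.sum() == 10
        assert np.allclose(freqs[sw, 1], 0.9, atol=1e-5)
        assert np.allclose(freqs[sw, 0], 0.1, atol=1e-5)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _cfg(fst_target=(1.0, 0.0))
        with pytest.raises(ValueError):
            _cfg(n_sites=0)

    def test_paralog_flag_count_exact(self):
        cfg = _cfg(paralog_fraction=0.1)
        _, truth = simulate_allele_frequencies(cfg)
        assert truth.sites["is_paralog"].sum() == round(0.1 * cfg.n_sites)


class TestReads:
    def test_zero_error_hom_major_reads_all_major(self):
        cfg = _cfg(error_rate=0.0, ancestral_maf_range=(0.3, 0.4),
                   depth_lambda=5.0)
        freqs, truth = simulate_allele_frequencies(cfg)
        counts, truth = simulate_reads(freqs, cfg, truth)
        maj = truth.sites["major"].map(
            {b: i for i, b in enumerate("ACGT")}
        ).to_numpy()
        mino = truth.sites["minor"].map(
            {b: i for i, b in enumerate("ACGT")}
        ).to_numpy()
        hom_major = truth.genotypes == 0
        S, N = truth.genotypes.shape
        for s in range(S):
            other = [b for b in range(4) if b != maj[s]]
            off = counts[s, :, other].sum(axis=0)
            assert np.all(off[hom_major[s]] == 0)

    def test_poisson_depth_mean(self):
        cfg = _cfg(n_sites=2500, chrom_lengths={"chr1": 10**7},
                   depth_lambda=2.0)
        freqs, truth = simulate_allele_frequencies(cfg)
        counts, _ = simulate_reads(freqs, cfg, truth)
        # 2500 sites x 20 individuals = 50,000 Poisson draws.
        assert counts.sum() / (2500 * 20) == pytest.approx(2.0, rel=0.02)

    def test_paralog_sites_show_heterozygote_excess(self):
        # Mixed reads from two independent loci at freq ~0.5 mimic excess
        # heterozygosity relative to HWE at high depth.
        cfg = _cfg(n_sites=400, paralog_fraction=0.5, depth_lambda=40.0,
                   error_rate=0.0, ancestral_maf_range=(0.45, 0.5),
                   fst_target=(0.0, 0.0), seed=7)
        freqs, truth = simulate_allele_frequencies(cfg)
        counts, truth = simulate_reads(freqs, cfg, truth)
        from glpopgen.glcore import BASE_INDEX, gl_from_counts

        maj = truth.sites["major"].map(BASE_INDEX).to_numpy()
        mino = truth.sites["minor"].map(BASE_INDEX).to_numpy()
        gls = gl_from_counts(counts, maj, mino, 0.001)
        called = gls.argmax(axis=2)
        par = truth.sites["is_paralog"].to_numpy()
        het_par = (called[par] == 1).mean()
        het_norm = (called[~par] == 1).mean()
        assert het_par > het_norm + 0.1

    def test_realized_fst_consistent_with_genotype_estimate(self):
        cfg = _cfg(n_sites=4000, chrom_lengths={"chr1": 10**7},
                   pop_sizes=(50, 50), fst_target=(0.05, 0.05), seed=5)
        freqs, truth = simulate_allele_frequencies(cfg)
        _, truth = simulate_reads(freqs, cfg, truth)
        from glpopgen.differentiation import hudson_site, weighted_fst

        g = truth.genotypes
        p1 = g[:, :50].sum(axis=1) / 100.0
        p2 = g[:, 50:].sum(axis=1) / 100.0
        num, den = hudson_site(p1, 100, p2, 100)
        est = weighted_fst(num, den)
        assert est == pytest.approx(truth.fst_true["fst"].iloc[0], abs=0.015)


class TestMito:
    def test_no_mutations_single_haplotype(self):
        cfg = _cfg(mito_mutations=0.0)
        _, haps, seqs = simulate_mito_alignment(cfg)
        assert haps["haplotype"].nunique() == 1
        assert len(set(seqs.values())) == 1

    def test_seeded_run_reproducible(self):
        cfg = _cfg(mito_mutations=8.0, seed=9)
        c1, h1, s1 = simulate_mito_alignment(cfg)
        c2, h2, s2 = simulate_mito_alignment(cfg)
        assert np.array_equal(c1, c2)
        assert h1.equals(h2)
        assert s1 == s2

    def test_expected_pairwise_differences_scale(self):
        cfg = _cfg(mito_mutations=10.0, mito_length=2000,
                   pop_sizes=(25, 25), seed=3)
        _, _, seqs = simulate_mito_alignment(cfg)
        arr = np.array([list(s) for s in seqs.values()])
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(300):
            i, j = rng.choice(len(arr), 2, replace=False)
            diffs.append((arr[i] != arr[j]).sum())
        # Coalescent variance is large; just require the right order.
        assert 2.0 < np.mean(diffs) < 40.0


class TestDeterminism:
    def test_fixed_seed_identical_different_seed_differs(self):
        cfg = _cfg(seed=21)
        f1, t1 = simulate_allele_frequencies(cfg)
        f2, t2 = simulate_allele_frequencies(cfg)
        assert np.array_equal(f1, f2)
        assert t1.sites.equals(t2.sites)
        f3, _ = simulate_allele_frequencies(_cfg(seed=22))
        assert not np.array_equal(f1, f3)
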