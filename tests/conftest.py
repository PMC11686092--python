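"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from glpopgen.simdata import SimConfig, simulate_allele_frequencies, simulate_reads


def degenerate_gls(genotypes: np.ndarray) -> np.ndarray:
    """(S, N) genotype matrix -> (S, N, 3) certain (one-hot) GL triples."""
    S, N = genotypes.shape
    gls = np.zeros((S, N, 3))
    s, n = np.meshgrid(np.arange(S), np.arange(N), indexing="ij")
    gls[s, n, genotypes] = 1.0
    return gls


@pytest.fixture(scope="session")
def two_pop_deep():
    """Two populations, 12 diploids each, 400 SNPs at 20x: informative GLs."""
    cfg = SimConfig(
        n_pops=2, pop_sizes=(12, 12), pop_names=("P1", "P2"),
        n_sites=400, chrom_lengths={"chr1": 500_000},
        fst_target=(0.15, 0.15), depth_lambda=20.0, error_rate=0.01,
        sweep_region=None, paralog_fraction=0.0,
        mito_length=200, seed=11,
    )
    freqs, truth = simulate_allele_frequencies(cfg)
    counts, truth = simulate_reads(freqs, cfg, truth)
    from glpopgen.glcore import BASE_INDEX, GLMatrix, gl_from_counts

    maj = truth.sites["major"].map(BASE_INDEX).to_numpy()
    mino = truth.sites["minor"].map(BASE_INDEX).to_numpy()
    gls = gl_from_counts(counts, maj, mino, cfg.error_rate)
    gl = GLMatrix(truth.sites[["chrom", "pos", "major", "minor"]].copy(),
                  cfg.individuals(), gls)
    return cfg, gl, counts, truth
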