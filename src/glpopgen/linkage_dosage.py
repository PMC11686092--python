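"""Linkage disequilibrium from genotype likelihoods, and dosage polarization.

LD between two biallelic sites is estimated without phase or hard genotype
calls: an EM over the four haplotype frequencies (AB, Ab, aB, ab) treats each
individual's two-site genotype as unobserved, weighting every ordered pair of
haplotypes by the product of the current frequencies and the individual's
genotype likelihoods, and renormalizing expected haplotype counts - the
standard unphased double-heterozygote split, generalized to soft genotypes.
r^2 = D^2 / (pA(1-pA) pB(1-pB)) with D = f(AB) - pA pB.

The dosage matrix projects each individual's GL triple at outlier SNPs onto a
0-2 scale relative to a reference population: values near 2 and 0 mean
likely homozygosity (for the reference-major and the alternative allele) and
values near 1 likely heterozygosity; an uninformative triple (all ~1/3, i.e.
no reads) is missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .glcore import GLMatrix, UNIFORM_TOL

__all__ = ["LinkagePair", "haplotype_em_r2", "ld_matrix", "dosage_matrix"]

# Ordered haplotypes: 0=AB, 1=Ab, 2=aB, 3=ab (A/B = major alleles).
_HAP_G1 = np.array([0, 0, 1, 1])  # minor-allele copies at site 1 per haplotype
_HAP_G2 = np.array([0, 1, 0, 1])


@dataclass
class LinkagePair:
    pos_i: int
    pos_j: int
    dist: int
    hap_freqs: np.ndarray  # (AB, Ab, aB, ab)
    D: float
    D_prime: float
    r2: float
    loglik: float
    converged: bool


def _pair_genotype_index() -> tuple[np.ndarray, np.ndarray]:
    """Genotype (site1, site2) implied by each ordered haplotype pair (16,)."""
    pairs = np.array(list(product(range(4), repeat=2)))
    g1 = _HAP_G1[pairs[:, 0]] + _HAP_G1[pairs[:, 1]]
    g2 = _HAP_G2[pairs[:, 0]] + _HAP_G2[pairs[:, 1]]
    return pairs, np.stack([g1, g2], axis=1)


_PAIRS, _PAIR_GENO = _pair_genotype_index()


def haplotype_em_r2(
    gl_i: np.ndarray,
    gl_j: np.ndarray,
    pos_i: int = 0,
    pos_j: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LinkagePair:
    """Two-locus haplotype-frequency EM and r^2 for one site pair.

    ``gl_i``, ``gl_j`` are (N, 3) normalized GL triples at the two sites
    (ordered hom-major, het, hom-minor with the site's own major allele).
    """
    gl_i = np.asarray(gl_i, dtype=float)
    gl_j = np.asarray(gl_j, dtype=float)
    N = gl_i.shape[0]
    # Per-individual likelihood of each of the 16 ordered haplotype pairs.
    lik_pairs = gl_i[:, _PAIR_GENO[:, 0]] * gl_j[:, _PAIR_GENO[:, 1]]  # (N, 16)
    h = np.full(4, 0.25)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        w = lik_pairs * (h[_PAIRS[:, 0]] * h[_PAIRS[:, 1]])[None, :]
        tot = w.sum(axis=1)  # (N,)
        ll = float(np.log(np.maximum(tot, 1e-300)).sum())
        post = w / np.maximum(tot, 1e-300)[:, None]
        counts = np.zeros(4)
        for hap in range(4):
            counts[hap] = post[:, _PAIRS[:, 0] == hap].sum() + post[
                :, _PAIRS[:, 1] == hap
            ].sum()
        h = counts / (2.0 * N)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    pA = h[0] + h[1]  # major-allele frequency at site 1
    pB = h[0] + h[2]
    D = h[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = float(D**2 / denom) if denom > 0 else float("nan")
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = float(abs(D) / dmax) if dmax > 0 else float("nan")
    return LinkagePair(pos_i, pos_j, abs(pos_j - pos_i), h, float(D),
                       d_prime, min(r2, 1.0), ll, converged)


def ld_matrix(
    gl: GLMatrix,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    max_dist: int = 100_000,
    subsample_every: int = 10,
) -> pd.DataFrame:
    """All-pairs LD within a region after systematic SNP thinning.

    Keeps every ``subsample_every``-th SNP (offset 0 - deterministic), then
    computes the haplotype EM for every retained pair within ``max_dist`` bp.
    Returns a DataFrame (pos_i, pos_j, dist, D, D_prime, r2).
    """
    sites = gl.sites
    mask = np.ones(len(sites), dtype=bool)
    if chrom is not None:
        mask &= (sites["chrom"] == chrom).to_numpy()
        if start is not None:
            mask &= (sites["pos"] >= start).to_numpy()
        if end is not None:
            mask &= (sites["pos"] <= end).to_numpy()
    idx = np.flatnonzero(mask)[::subsample_every]
    rows = []
    pos = sites["pos"].to_numpy()
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            d = abs(int(pos[j]) - int(pos[i]))
            if d > max_dist:
                break  # positions sorted within a chromosome
            pair = haplotype_em_r2(gl.gls[i], gl.gls[j], int(pos[i]), int(pos[j]))
            rows.append(
                {"pos_i": pair.pos_i, "pos_j": pair.pos_j, "dist": pair.dist,
                 "D": pair.D, "D_prime": pair.D_prime, "r2": pair.r2}
            )
    return pd.DataFrame(rows, columns=["pos_i", "pos_j", "dist", "D",
                                       "D_prime", "r2"])


def dosage_matrix(
    gl: GLMatrix, snp_mask: np.ndarray | None = None,
    reference_pop: str = "GOA",
) -> pd.DataFrame:
    """Reference-polarized allele dosages for a set of SNPs.

    Per SNP, the reference-major homozygote class is the homozygote (index 0
    or 2 of the GL triple) with the larger mean normalized GL over the
    reference population's individuals with data.  Each individual's dosage
    is then GL(het) + 2 * GL(hom reference-major); a uniform triple is NA.

    Returns a long-format DataFrame (chrom, pos, id, pop, dosage) with NaN
    for missing dosages; heatmap-ready.
    """
    pops = gl.pop_indices()
    if reference_pop not in pops:
        raise ValueError(f"reference population {reference_pop!r} not present")
    if snp_mask is None:
        snp_mask = np.ones(gl.n_sites, dtype=bool)
    snp_idx = np.flatnonzero(snp_mask)
    ref_cols = pops[reference_pop]
    missing = gl.missing_mask()
    recs = []
    ids = gl.individuals["id"].to_numpy()
    pop_labels = gl.individuals["pop"].to_numpy()
    chroms = gl.sites["chrom"].to_numpy()
    positions = gl.sites["pos"].to_numpy()
    for s in snp_idx:
        ref_data = ~missing[s, ref_cols]
        if not ref_data.any():
            continue  # no reference information: drop the column
        ref_gls = gl.gls[s, ref_cols[ref_data]]
        hom_class = 0 if ref_gls[:, 0].mean() >= ref_gls[:, 2].mean() else 2
        dose = gl.gls[s, :, 1] + 2.0 * gl.gls[s, :, hom_class]
        dose = np.where(missing[s], np.nan, dose)
        recs.append(
            pd.DataFrame(
                {"chrom": chroms[s], "pos": positions[s], "id": ids,
                 "pop": pop_labels, "dosage": dose}
            )
        )
    if not recs:
        return pd.DataFrame(columns=["chrom", "pos", "id", "pop", "dosage"])
    return pd.concat(recs, ignore_index=True)
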