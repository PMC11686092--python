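"""Genotype-likelihood LD (haplotype EM r^2) and dosage polarization."""

import numpy as np
import pandas as pd

from glpopgen.glcore import GLMatrix
from glpopgen.linkage_dosage import dosage_matrix, haplotype_em_r2, ld_matrix

# --- LD: two perfectly correlated sites vs two independent sites -----------
rng = np.random.default_rng(2)
haps = rng.integers(0, 2, size=(20, 2))
g_corr = haps.sum(axis=1)  # same haplotype at both loci


def one_hot(g):
    out = np.zeros((len(g), 3))
    out[np.arange(len(g)), g] = 1.0
    return out


pair = haplotype_em_r2(one_hot(g_corr), one_hot(g_corr))
print(f"perfectly correlated sites: r^2 = {pair.r2:.3f}, D' = {pair.D_prime:.3f}")
g_other = rng.binomial(2, 0.5, size=20)
pair2 = haplotype_em_r2(one_hot(g_corr), one_hot(g_other))
print(f"independent sites:          r^2 = {pair2.r2:.3f}")
print("-> r^2 near 1 means the two SNPs travel on the same haplotypes\n")

# --- Dosage polarization ---------------------------------------------------
gls = np.array([[[1 / 3, 1 / 3, 1 / 3],  # no reads -> NA
                 [1.0, 0.0, 0.0],        # hom for reference-major -> 2
                 [0.0, 1.0, 0.0],        # het -> 1
                 [0.0, 0.0, 1.0]]])      # hom alternative -> 0
gl = GLMatrix(
    pd.DataFrame({"chrom": ["chr1"], "pos": [500],
                  "major": ["A"], "minor": ["C"]}),
    pd.DataFrame({"id": ["missing", "homref", "het", "homalt"],
                  "pop": ["GOA", "GOA", "other", "other"]}),
    gls,
)
dm = dosage_matrix(gl, reference_pop="GOA")
print(dm[["id", "pop", "dosage"]].to_string(index=False))
print("\nDosages polarize every individual against the reference population's")
print("major homozygote: 2 = that homozygote, 1 = het, 0 = the other, NA = no data.")
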