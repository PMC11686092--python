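"""Local PCA + MDS scan for haploblocks (regions of atypical covariance).

A simulated 'inversion': every SNP in one span shares the same three-cluster
genotype pattern across individuals.  Its windows land far from the pack in
MDS space and get flagged.
"""

import numpy as np
import pandas as pd

from glpopgen.glcore import GLMatrix
from glpopgen.localpca import local_pca_scan

rng = np.random.default_rng(1)
S, N = 2000, 24
f = rng.uniform(0.2, 0.5, size=S)
g = rng.binomial(2, f[:, None], size=(S, N))
hap_genotype = rng.integers(0, 3, size=N)  # per-individual inversion genotype
g[1000:1200] = hap_genotype  # the haploblock span

gls = np.zeros((S, N, 3))
s_idx, n_idx = np.meshgrid(np.arange(S), np.arange(N), indexing="ij")
gls[s_idx, n_idx, g] = 1.0
gl = GLMatrix(
    pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, S + 1) * 100,
                  "major": "A", "minor": "C"}),
    pd.DataFrame({"id": [f"i{k}" for k in range(N)], "pop": "x"}),
    gls,
)

df = local_pca_scan(gl, window_snps=100, mds_dims=5)
print(df[["start", "end", "mds1", "outlier"]].round(3).to_string(index=False))
flagged = df.loc[df["outlier"], ["start", "end"]]
print(f"\nflagged windows:\n{flagged.to_string(index=False)}")
print("\nThe haploblock spans positions 100100-120000; its windows separate")
print("on MDS axis 1 because their covariance is dominated by the three")
print("discrete inversion genotypes instead of genome-wide relatedness.")
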