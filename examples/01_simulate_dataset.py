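"""Generate a small synthetic low-coverage dataset with known truth.

Five populations diverged under the Balding-Nichols model, sequenced at ~2x
with 1% base errors; the truth tables record every frequency and genotype so
downstream estimators can be scored.
"""

from glpopgen.simdata import SimConfig, simulate_dataset

config = SimConfig(
    n_pops=5,
    pop_sizes=(10, 10, 10, 10, 10),
    n_sites=2000,
    chrom_lengths={"chr1": 500_000, "chr2": 500_000},
    sweep_region=("chr2", 200_000, 300_000, (0.0, 0.0, 0.0, 0.8, 0.0)),
    seed=42,
)
gl, mito_counts, truth = simulate_dataset(config, outdir="example_out/simulated")

print(f"sites x individuals: {gl.n_sites} x {gl.n_individuals}")
print(f"sweep-flagged SNPs: {truth.sites['is_sweep'].sum()}")
print(f"paralog-flagged SNPs: {truth.sites['is_paralog'].sum()}")
print("\nrealized pairwise Hudson FST (from true frequencies):")
print(truth.fst_true.to_string(index=False))
print("\nThe FST values sit on the weak-differentiation scale (1e-3..1e-2)")
print("typical of high-gene-flow marine species; the sweep block on chr2")
print("is the one deliberately differentiated region.")
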