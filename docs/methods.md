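# Methods

This note records the statistical models, numerical choices and known
limitations of `glpopgen`, in the order data flows through the pipeline.

## Genotype likelihoods (glcore)

Per-read model: a read showing base *b* under true allele *a* has probability
1−ε if b = a and ε/3 otherwise; a diploid genotype averages its two alleles
and the site likelihood is the product over reads, restricted to the three
genotypes over the site's (major, minor) pair and normalized to sum to 1.
Raw log-likelihoods are kept internally (shifted by their maximum before
exponentiation) so deep sites do not underflow. An individual with zero
reads receives (1/3, 1/3, 1/3); the pipeline-wide missing-data rule is
"all three entries within 1e−3 of 1/3", matching the two-decimal 0.33
convention of Beagle-GL text files. Base quality is a single per-run ε
rather than per-read qualities — this keeps a closed-form oracle for every
test; per-read qualities are accepted by the scalar API
(`genotype_likelihood`) but the simulator does not emit them.

Consequence used widely in tests: for a single read the het likelihood is
the mean of the two homozygote likelihoods, so its normalized value is
exactly 1/3 regardless of ε.

## Site filtering (filters)

MAF is estimated per site by EM under the HWE prior
P(g|f) = ((1−f)², 2f(1−f), f²); the update is the posterior-mean allele
count over 2N. Convergence |Δf| < 1e−8, ≤200 iterations; the likelihood is
non-decreasing (standard EM), and a column of uniform triples is reported
undefined. SNP calling uses LR = 2[lnL(f̂) − lnL(monomorphic)] against
χ²(1), with the monomorphic null taken as the better of f = 0 and f = 1.
MAF is reported folded (≤0.5) with major/minor relabelled; ties at 0.5 break
alphabetically (A<C<G<T).

The paralog (mismapping) filter refits each polymorphic site with
P(g|f,F) = ((1−f)²+f(1−f)F, 2f(1−f)(1−F), f²+f(1−f)F), F free on
[max(−1, validity bound), 1]; reads pooled from a duplicated locus mimic
F < 0 (excess heterozygosity). The log-likelihood is concave in F (log of a
linear function per individual), so the maximizer is found by vectorized
ternary search (40 iterations, interval ~1e−7). LR vs F = 0 is referred to
χ²(1); when F̂ sits on a boundary the ½χ²₀+½χ²₁ mixture halves the p-value.
Bonferroni correction runs over tested (polymorphic) sites; sites with
adjusted p below α are excluded. A config switch reproduces the literal
"exclude adjusted p above α" reading of the source pipeline's description,
which we take to be a wording slip.

Depth bounds (defaults 183/3660) are totals over individuals and should be
rescaled for differently sized datasets (the demo uses 50/1500 for
75 individuals at 2×). Whether the original bounds were per-site totals is
not derivable from the numbers alone; totals are assumed and configurable.

## Structure (structure)

PCA: posterior-mean dosages ê under the HWE prior at f̂ are standardized as
(ê − 2f̂)/√(2f̂(1−f̂)) and averaged over sites into an N×N covariance;
eigendecomposition via `numpy.linalg.eigh`. Percent variance is reported
over all PCs. Sites within 1e−4 of fixation are skipped (vanishing
denominator). Region-balanced subsampling (default 16 per population,
seeded) counters sample-size distortion of PC space. The iterative
individual-allele-frequency refinement used by PCAngsd is not implemented;
the posterior-mean covariance is deterministic and oracle-testable, which is
what the test surface needs.

Admixture: EM on expected allele-copy counts for
π_is = Σ_k Q_ik F_sk with the binomial genotype prior; F and Q updates use
the same E-step quantities, so the likelihood is monotone. Parameters are
clipped to [1e−6, 1−1e−6]; convergence ΔlogL < 1e−5; restart r uses seed
base+r and the best log-likelihood wins (default 10 restarts; the demo uses
2). K = 1 is closed-form (Q ≡ 1, F = EM MAF). AICc uses
p = N(K−1) + S·K and n = N·S — the parameter count is not uniquely
standard; it is logged in the output table and configurable in the sense
that the table exposes p so any other penalty can be recomputed.

## Diversity (diversity)

Sample-allele-count likelihoods P(data|j), j = 0..2N, are built by DP over
individuals with per-genotype weights GL_g·C(2,g), divided by C(2N,j) and
max-normalized per site (per-site constants are irrelevant to the EMs that
consume them). Folding sums j with 2N−j. With degenerate (0/1) GLs the
vector is a point mass at the true count — this exactness is the test
surface. The spectrum η maximizes Σ_s log Σ_j η_j P(data_s|j) by EM
(ΔlogL < 1e−6), reported on the counts scale (Ση = S).

Per-site θ statistics use the global spectrum as an empirical-Bayes prior:
post_j ∝ η_j P(data_s|j); π_s = Σ_j [j(2N−j)/C(2N,2)]·post_j,
θW,s = (1−post₀)/a₁. Windows are 1-based inclusive, anchored at 1,
advancing by `step` (defaults 5000/1000); the window that reaches the
chromosome end is clipped, kept, and flagged partial. Tajima's D uses the
1989 constants with n = 2N and S* = Σ(1−post₀); D is undefined (NaN) when
S* ≈ 0. This posterior-weighted construction is an approximation to exact
per-site theta machinery, but is exact in the known-genotype limit, where
the tests pin it to O(N²) pairwise and textbook-constant oracles at 1e−10.

Inbreeding: per individual, EM on the mixture reading of
P(g|f,F) = F·IBD(g|f) + (1−F)·HWE(g|f) with IBD = (1−f, 0, f), F ∈ [0,1]
(the shared negative-F machinery lives in the paralog test). Individuals
with fewer than 50 informative sites are flagged low-confidence.

Window comparison: pooled-variance two-sample t by default (Welch optional),
with the difference CI. Overlapping sliding windows are autocorrelated, so
the nominal p-value is anti-conservative; the docstring flags this and the
pipeline reports it as approximate.

## Differentiation (differentiation)

Hudson per-site numerator/denominator as in the README; multi-site FST is
strictly Σnum/Σden (ratio of sums), never a mean of ratios. Negative
numerators are retained; sites with den = 0 or with fewer than 2 genotyped
individuals in either population are skipped. Frequencies come from
per-population EM on the GLs under the shared global polarization, with
n = 2 × individuals with data. A 2D-SFS-based estimator is a possible
extension; the EM-frequency route is deterministic and directly checkable
against genotype-count oracles. Note the estimator's finite-sample
behaviour: two literally identical samples give −1/(n−1), not 0.

## Selection scan (scan)

FET p-values are computed by full hypergeometric enumeration (sum of tables
with pmf ≤ observed, with a 1+1e−7 tie tolerance), vectorized over tables;
`scipy.stats.fisher_exact` is the independent oracle in tests. Allele
counts per population are read-backed (summed over individuals, keeping
only reads matching the two alleles), mirroring per-region count dumps with
no individual resolution; at depth >1× such reads are pseudo-replicated, so
a genotype-posterior-count mode would be a reasonable alternative input —
the scan operates on whatever p-values it is given.

Scores s = −log₁₀(p) − ξ (p floored at 1e−300), Lindley
h_i = max(0, h_{i−1} + s_i). Per-chromosome thresholds: the k-th largest
max-Lindley over B seeded permutations of that chromosome's scores, with
k = ⌊α(B+1)⌋, and significance requires the observed maximum to STRICTLY
exceed it. This order-statistic/strict-inequality convention is the exact
permutation test: the max-Lindley permutation distribution has large atoms
(the maximum usually equals the largest single score, which reordering
cannot change), and a plain (1−α) quantile with ≥ comparison over-rejects
several-fold. Empirical check: 0.01 exceedance at α = 0.01 over 500 null
chromosomes (this is acceptance target t2). A Gumbel fit to the permuted
maxima is the fast alternative. Regions are maximal h > 0 runs containing
an exceedance, reported first-to-last SNP, 1-based inclusive; chromosomes
with <10 SNPs are skipped.

## Local PCA (localpca)

Windows are SNP-count blocks (default 100 SNPs) because 1000 bp windows at
~2× lcWGS density contain too few SNPs for a stable covariance; bp windows
remain available behind `window_bp`. Each window's covariance is normalized
to unit trace and reduced to rank k (default 2); D(w₁,w₂) is the Frobenius
norm between the rank-k approximations — the cheap surrogate for a full
Euclidean distance between covariance structures. Classical (Torgerson) MDS
embeds D; windows beyond 3 robust SDs (median/MAD × 1.4826) on any retained
axis are flagged. The robust scale matters: a handful of extreme haploblock
windows inflate a plain SD enough to mask themselves (max |z| is bounded by
(W−1)/√W for W windows); `robust=False` restores the plain rule.

## LD and dosage (linkage_dosage)

Two-locus haplotype EM over (AB, Ab, aB, ab): each individual's 16 ordered
haplotype pairs are weighted by current frequencies times the product of the
two sites' GLs at the implied genotypes, and expected haplotype counts are
renormalized — the classic unphased double-heterozygote split generalized
to soft genotypes. r² = D²/(p_A(1−p_A)p_B(1−p_B)), D' = |D|/D_max. With
degenerate GLs and no double heterozygotes the EM equals direct counting
exactly; with double hets it returns the MLE, which the tests score against
known simulated haplotypes (RMSE < 0.05 at 20×). Region LD uses systematic
1-in-10 SNP thinning (offset 0 — deterministic by design) and a 100 kb
distance cap.

Dosage: per SNP the reference-major homozygote class is the homozygote with
the larger mean normalized GL over reference-population individuals with
data ("mean GL of the major homozygous allele" read as a class choice —
the wording is compressed); each individual then gets
GL(het) + 2·GL(hom ref-major), NA if its triple is uniform (the NA rule is
applied per individual before any averaging). Dosage is always in [0,2] and
flipping the reference class maps d → 2−d at degenerate sites.

## Mitochondria (mito)

Consensus: majority base iff depth ≥ 4 and majority fraction ≥ 0.75; ties
and failures are N (conservative). Haplotype collapsing defaults to global
masking — sites with an N in any individual are excluded before comparing —
because pairwise N-wildcard matching can make "identity" intransitive; the
pairwise mode exists but raises if it would produce an inconsistent
partition. Hd = n(1−Σp²)/(n−1), undefined for populations of one. The
network is the minimum spanning tree on pairwise base differences
(networkx), plus alternative links for non-MST pairs whose direct distance
equals the total MST-path distance (an equally parsimonious connection).
A coordinate-range slice (e.g. a single gene such as COI) is the same
machinery on a sub-alignment, not separate code.

## Synthetic data (simdata)

What it emulates: five populations at the study's sample sizes
(28/45/44/35/16), Balding–Nichols frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p ~ Uniform(0.05, 0.5) with
per-population F = (0.003, 0.001, 0.001, 0.010, 0.005) — pairwise FST
≈ (F_i+F_j)/2 spans the observed ~0.001–0.013 scale with the fourth
population (the SEAK analogue) most distinct; HWE genotypes; Poisson 2×
depth; ε = 0.01 (Q20) errors; one 20-SNP sweep block with a +0.8 frequency
offset in one population (soft-sweep-like: frequencies shifted, no forced
LD block); 5% of sites drawing half their reads from an independent
second-locus genotype (collapsed paralogs); mitochondrial haplotypes on a
hand-rolled Kingman coalescent with Poisson mutations scaled so a random
pair differs at `mito_mutations` (default 10) sites, sequenced at 50×.
Positions are uniform per chromosome, sorted, 1-based.

What it does not emulate: linkage disequilibrium from shared genealogy
along chromosomes (sites are independent given frequencies), recombination,
per-read quality variation, indels, mapping artefacts beyond the paralog
mixture, and a realistic (neutral-coalescent) site-frequency spectrum —
ancestral frequencies are uniform, which inflates intermediate-frequency
variants and makes Tajima's D positive genome-wide. Passing tests therefore
demonstrate estimator correctness under the stated models, not robustness
to real-data artefacts upstream of the per-site counts interface.

Scale choices: the end-to-end demo runs 5 populations × 15 individuals ×
20,000 SNPs over 10 chromosomes with admixture on a 2,000-site thinned
subset (K = 1–3, 2 restarts, ≤300 iterations) and 200 scan permutations —
sizes chosen so the whole demo runs in minutes on one CPU while every stage
still has enough signal to be meaningfully checked. Test simulations are
similarly desk-scale (hundreds to thousands of sites) with tolerances
derived from the corresponding binomial/Monte-Carlo error, not tuned.

## Determinism

All randomness flows through `numpy.random.default_rng` generators derived
from the single run seed and a stage name (CRC-based sub-seeds below 2³¹),
so stages are independently reproducible and adding a stage never perturbs
another's stream. Output files use fixed float formats and LF endings; the
pipeline manifest records SHA-256 hashes of every artifact, and a rerun
with the same seed is byte-identical (tested).

## Known limitations

* Admixture EM is plain EM (no acceleration); hard Ks on large S are slow,
  hence the site-thinning knob.
* The t test on overlapping windows ignores autocorrelation (flagged).
* The paralog filter is an excess-heterozygosity proxy for a full
  duplication/mismapping model; the model hook is pluggable.
* No BAM/pileup ingestion: the pipeline starts at per-site base counts or
  Beagle-GL files by design.
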