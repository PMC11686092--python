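"""Synthetic low-coverage WGS datasets with known truth.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* five populations with the study's sample sizes (28/45/44/35/16 diploids),
* population allele frequencies diverged from a shared ancestral frequency
  under the Balding-Nichols model, with per-population F parameters on the
  weak-differentiation scale (FST of order 1e-3 .. 1e-2) typical of
  high-gene-flow marine invertebrates,
* Poisson read depth (default mean 2x per individual, matching low-coverage
  whole-genome designs), with Q20-scale base-calling errors,
* one injected high-differentiation "sweep" block of contiguous SNPs,
* a fraction of sites contaminated by reads from a duplicated paralogous
  locus (producing apparent excess heterozygosity), and
* mitochondrial haplotypes generated on a random Kingman coalescent
  genealogy and sequenced at high depth.

Every quantity needed to score an estimator afterwards (true frequencies,
genotypes, realized FST, sweep/paralog flags, mito haplotypes) is recorded in
a :class:`TruthTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import stage_rng
from .glcore import BASES, GLMatrix, gl_from_counts, write_beagle, write_counts_tsv

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_allele_frequencies",
    "simulate_reads",
    "simulate_mito_alignment",
    "simulate_dataset",
]

#: Diploid sample sizes of the five study regions (Nor/Chu, EBS, GOA, SEAK, AIs).
STUDY_POP_SIZES = (28, 45, 44, 35, 16)
STUDY_POP_NAMES = ("NorChu", "EBS", "GOA", "SEAK", "AIs")


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults reproduce the study design: five regional populations at the
    published sample sizes, divergence on the observed FST scale, ~2x mean
    depth and Q20 (1%) base errors, a 20-SNP sweep block on one chromosome
    with a +0.8 frequency offset in a single population, and 5% of sites
    behaving as collapsed paralogs.
    """

    n_pops: int = 5
    pop_sizes: tuple[int, ...] = STUDY_POP_SIZES
    pop_names: tuple[str, ...] = STUDY_POP_NAMES
    n_sites: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_000_000 for i in range(1, 21)}
    )
    # Per-pop Balding-Nichols F; pairwise FST ~ (F_i + F_j)/2 spans ~1e-3..1e-2.
    fst_target: tuple[float, ...] = (0.003, 0.001, 0.001, 0.010, 0.005)
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    depth_lambda: float = 2.0
    error_rate: float = 0.01  # Q20
    # (chrom, start bp, end bp, per-pop frequency offsets)
    sweep_region: tuple[str, int, int, tuple[float, ...]] | None = (
        "chr20",
        400_000,
        500_000,
        (0.0, 0.0, 0.0, 0.8, 0.0),
    )
    sweep_n_snps: int = 20
    paralog_fraction: float = 0.05
    mito_length: int = 2_000
    mito_mutations: float = 10.0
    mito_depth: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("all pop_sizes must be >= 1")
        if len(self.fst_target) != self.n_pops:
            raise ValueError("fst_target needs one F per population")
        if not all(0.0 <= f < 1.0 for f in self.fst_target):
            raise ValueError("fst_target values must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))

    def individuals(self) -> pd.DataFrame:
        ids, pops = [], []
        for name, size in zip(self.pop_names, self.pop_sizes):
            for i in range(size):
                ids.append(f"{name}_{i + 1:03d}")
                pops.append(name)
        return pd.DataFrame({"id": ids, "pop": pops})

    def pop_of_individual(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_pops), self.pop_sizes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        for key in ("pop_sizes", "pop_names", "fst_target", "ancestral_maf_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "sweep_region" in kwargs and kwargs["sweep_region"] is not None:
            c, s, e, off = kwargs["sweep_region"]
            kwargs["sweep_region"] = (c, int(s), int(e), tuple(off))
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Ground truth recorded alongside a synthetic dataset."""

    sites: pd.DataFrame  # chrom,pos,major,minor,ancestral_freq,is_sweep,is_paralog
    pop_freqs: np.ndarray  # (S, P) true minor-allele frequency per population
    paralog_freqs: np.ndarray | None = None  # (S, P) second-locus frequencies
    genotypes: np.ndarray | None = None  # (S, N) minor-allele copies in {0,1,2}
    fst_true: pd.DataFrame | None = None  # realized pairwise Hudson FST
    mito_haplotypes: pd.DataFrame | None = None  # individual -> haplotype id
    mito_sequences: dict[str, str] | None = None

    def write(self, outdir: str | Path, individuals: pd.DataFrame | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        truth_sites = self.sites.copy()
        for p in range(self.pop_freqs.shape[1]):
            truth_sites[f"freq_pop{p}"] = self.pop_freqs[:, p]
        truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False,
                           lineterminator="\n", float_format="%.6f")
        if self.genotypes is not None and individuals is not None:
            geno = pd.DataFrame(
                self.genotypes, columns=individuals["id"].tolist()
            )
            geno.insert(0, "pos", self.sites["pos"].to_numpy())
            geno.insert(0, "chrom", self.sites["chrom"].to_numpy())
            geno.to_csv(outdir / "truth_genotypes.tsv", sep="\t", index=False,
                        lineterminator="\n")
        if self.fst_true is not None:
            self.fst_true.to_csv(outdir / "truth_fst.tsv", sep="\t", index=False,
                                 lineterminator="\n", float_format="%.8f")
        if self.mito_haplotypes is not None:
            self.mito_haplotypes.to_csv(
                outdir / "truth_mito_haplotypes.tsv", sep="\t", index=False,
                lineterminator="\n")
        if self.mito_sequences is not None:
            with open(outdir / "truth_mito.fasta", "w", newline="\n") as fh:
                for name, seq in self.mito_sequences.items():
                    fh.write(f">{name}\n{seq}\n")


def _site_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform random, sorted, unique 1-based SNP positions per chromosome."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n_sweep = 0
    sweep = config.sweep_region
    if sweep is not None:
        if sweep[0] not in config.chrom_lengths:
            raise ValueError(f"sweep chromosome {sweep[0]} not in chrom_lengths")
        n_sweep = config.sweep_n_snps
    n_background = config.n_sites - n_sweep
    if n_background < 0:
        raise ValueError("n_sites smaller than the sweep block")
    per_chrom = rng.multinomial(n_background, lengths / lengths.sum())
    rows: list[pd.DataFrame] = []
    for chrom, L, n in zip(chroms, lengths, per_chrom):
        pos = rng.choice(int(L), size=n, replace=False) + 1
        if sweep is not None and chrom == sweep[0]:
            _, start, end, _ = sweep
            span = end - start + 1
            spos = rng.choice(span, size=min(n_sweep, span), replace=False) + start
            pos = np.concatenate([pos[~np.isin(pos, spos)], spos])
        pos = np.sort(pos)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(np.int64)}))
    sites = pd.concat(rows, ignore_index=True)
    base_idx = rng.integers(0, 4, size=len(sites))
    minor_shift = rng.integers(1, 4, size=len(sites))
    minor_idx = (base_idx + minor_shift) % 4
    sites["major"] = [BASES[i] for i in base_idx]
    sites["minor"] = [BASES[i] for i in minor_idx]
    return sites


def _balding_nichols(
    p: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Population frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 copies p."""
    if F == 0.0:
        return p.copy()
    ratio = (1.0 - F) / F
    return rng.beta(p * ratio, (1.0 - p) * ratio)


def simulate_allele_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, TruthTable]:
    """Draw per-population minor-allele frequencies for every site.

    Returns the (S, P) frequency matrix and a TruthTable fragment holding the
    site table (with sweep and paralog flags), ancestral frequencies, and the
    second-locus frequencies used for paralog contamination.
    """
    if rng is None:
        rng = stage_rng(config.seed, "allele_frequencies")
    sites = _site_positions(config, rng)
    S, P = len(sites), config.n_pops
    lo, hi = config.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=S)
    freqs = np.empty((S, P))
    for k in range(P):
        freqs[:, k] = _balding_nichols(anc, config.fst_target[k], rng)

    is_sweep = np.zeros(S, dtype=bool)
    if config.sweep_region is not None:
        chrom, start, end, offsets = config.sweep_region
        in_region = (
            (sites["chrom"] == chrom)
            & (sites["pos"] >= start)
            & (sites["pos"] <= end)
        ).to_numpy()
        idx = np.flatnonzero(in_region)[: config.sweep_n_snps]
        is_sweep[idx] = True
        for k, off in enumerate(offsets):
            freqs[idx, k] = np.clip(freqs[idx, k] + off, 0.01, 0.99)

    n_paralog = int(round(config.paralog_fraction * S))
    eligible = np.flatnonzero(~is_sweep)
    paralog_idx = rng.choice(eligible, size=min(n_paralog, len(eligible)),
                             replace=False)
    is_paralog = np.zeros(S, dtype=bool)
    is_paralog[paralog_idx] = True
    # Independent second locus behind each paralog site, same divergence model.
    anc2 = rng.uniform(lo, hi, size=S)
    paralog_freqs = np.empty((S, P))
    for k in range(P):
        paralog_freqs[:, k] = _balding_nichols(anc2, config.fst_target[k], rng)

    sites = sites.assign(
        ancestral_freq=anc, is_sweep=is_sweep, is_paralog=is_paralog
    )
    return freqs, TruthTable(sites=sites, pop_freqs=freqs,
                             paralog_freqs=paralog_freqs)


def _parametric_hudson(p1: np.ndarray, p2: np.ndarray) -> float:
    """Infinite-sample Hudson FST (ratio of sums) from true frequencies."""
    num = (p1 - p2) ** 2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def realized_fst(config: SimConfig, freqs: np.ndarray) -> pd.DataFrame:
    rows = []
    for i in range(config.n_pops):
        for j in range(i + 1, config.n_pops):
            rows.append(
                {
                    "pop1": config.pop_names[i],
                    "pop2": config.pop_names[j],
                    "fst": _parametric_hudson(freqs[:, i], freqs[:, j]),
                }
            )
    return pd.DataFrame(rows)


def _scatter_reads(
    origin_idx: np.ndarray, n_reads: np.ndarray, error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Base counts (…, 4) for reads originating from a single true base.

    Each read stays on its origin base with probability 1-e and lands on a
    uniformly chosen other base otherwise.
    """
    shape = n_reads.shape
    correct = rng.binomial(n_reads, 1.0 - error_rate)
    n_err = n_reads - correct
    err_split = rng.multinomial(n_err.ravel(), [1 / 3] * 3).reshape(shape + (3,))
    # Column j of the permutation maps slot j to an actual base for each entry.
    others = np.stack([(origin_idx + s) % 4 for s in (1, 2, 3)], axis=-1)
    out = np.zeros(shape + (4,), dtype=np.int64)
    np.put_along_axis(out, origin_idx[..., None], correct[..., None], axis=-1)
    np.put_along_axis(out, others, err_split, axis=-1)
    return out


def simulate_reads(
    freqs: np.ndarray,
    config: SimConfig,
    truth: TruthTable,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, TruthTable]:
    """Simulate genotypes and per-site read counts for every individual.

    Genotypes are Hardy-Weinberg draws from each individual's population
    frequency; read depth is Poisson(depth_lambda); each read carries one of
    the genotype's alleles, corrupted at ``error_rate``.  At paralog-flagged
    sites half the reads come from an independent second-locus genotype.

    Returns the (S, N, 4) ACGT count array and the completed TruthTable.
    """
    if rng is None:
        rng = stage_rng(config.seed, "reads")
    S, P = freqs.shape
    N = config.n_individuals
    pop_of = config.pop_of_individual()
    f_ind = freqs[:, pop_of]  # (S, N)
    genotypes = rng.binomial(2, f_ind)  # minor-allele copies
    depth = rng.poisson(config.depth_lambda, size=(S, N))

    is_paralog = truth.sites["is_paralog"].to_numpy()
    depth_primary = depth.copy()
    depth_second = np.zeros_like(depth)
    if is_paralog.any():
        d_par = depth[is_paralog]
        d_a = rng.binomial(d_par, 0.5)
        depth_primary[is_paralog] = d_a
        depth_second[is_paralog] = d_par - d_a

    major_idx = truth.sites["major"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    minor_idx = truth.sites["minor"].map({b: i for i, b in enumerate(BASES)}).to_numpy()

    def _reads_for(geno: np.ndarray, d: np.ndarray) -> np.ndarray:
        from_minor = rng.binomial(d, geno / 2.0)
        from_major = d - from_minor
        maj = np.broadcast_to(major_idx[:, None], (S, N))
        mino = np.broadcast_to(minor_idx[:, None], (S, N))
        counts = _scatter_reads(maj, from_major, config.error_rate, rng)
        counts += _scatter_reads(mino, from_minor, config.error_rate, rng)
        return counts

    counts = _reads_for(genotypes, depth_primary)
    if is_paralog.any():
        f2 = truth.paralog_freqs[:, pop_of]
        genotypes2 = rng.binomial(2, f2)
        counts += _reads_for(genotypes2, depth_second)

    truth.genotypes = genotypes
    truth.fst_true = realized_fst(config, freqs)
    return counts, truth


# ---------------------------------------------------------------------------
# Mitochondrial simulation


def _kingman_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int, float]]:
    """Random Kingman coalescent over n tips.

    Returns edges (child, parent, branch_length) with tips 0..n-1; time is in
    coalescent units so a random pair coalesces at expected time 1.
    """
    active = list(range(n))
    times = {i: 0.0 for i in active}
    next_node = n
    t = 0.0
    edges: list[tuple[int, int, float]] = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent = next_node
        next_node += 1
        edges.append((a, parent, t - times[a]))
        edges.append((b, parent, t - times[b]))
        times[parent] = t
        active = [x for x in active if x not in (a, b)] + [parent]
    return edges


def simulate_mito_alignment(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame, dict[str, str]]:
    """High-depth mitochondrial base counts on a random genealogy.

    Haplotypes descend from a random ancestral sequence along a Kingman
    coalescent; mutations are Poisson on branches with the total rate chosen
    so a random pair of individuals differs at ``mito_mutations`` sites in
    expectation.  Sequencing is Poisson(``mito_depth``) per site with
    ``error_rate`` errors.

    Returns (counts (N, L, 4), haplotype table, true sequences by individual).
    """
    if rng is None:
        rng = stage_rng(config.seed, "mito")
    L = config.mito_length
    if L <= 0:
        raise ValueError("mito_length must be positive")
    N = config.n_individuals
    individuals = config.individuals()
    anc = rng.integers(0, 4, size=L)
    mu_total = config.mito_mutations / 2.0  # E[pair diff] = 2 * E[T2] * mu
    edges = _kingman_tree(N, rng)
    children: dict[int, list[tuple[int, float]]] = {}
    for child, parent, blen in edges:
        children.setdefault(parent, []).append((child, blen))
    root = max(parent for _, parent, _ in edges) if edges else 0
    seqs: dict[int, np.ndarray] = {root: anc}
    stack = [root]
    while stack:
        node = stack.pop()
        for child, blen in children.get(node, []):
            seq = seqs[node].copy()
            n_mut = rng.poisson(mu_total * blen)
            for _ in range(n_mut):
                pos = rng.integers(0, L)
                seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4
            seqs[child] = seq
            stack.append(child)

    tip_seqs = np.stack([seqs[i] for i in range(N)])  # (N, L)
    depth = rng.poisson(config.mito_depth, size=(N, L))
    counts = _scatter_reads(tip_seqs, depth, config.error_rate, rng)

    seq_strings = ["".join(BASES[b] for b in row) for row in tip_seqs]
    uniq: dict[str, int] = {}
    hap_ids = []
    for s in seq_strings:
        uniq.setdefault(s, len(uniq) + 1)
        hap_ids.append(f"H{uniq[s]}")
    hap_table = pd.DataFrame(
        {
            "id": individuals["id"],
            "pop": individuals["pop"],
            "haplotype": hap_ids,
        }
    )
    true_seqs = dict(zip(individuals["id"], seq_strings))
    return counts, hap_table, true_seqs


def simulate_dataset(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[GLMatrix, np.ndarray, TruthTable]:
    """Full synthetic dataset: frequencies, reads, GLs, mito, truth.

    If ``outdir`` is given, writes the Beagle GL file, the counts TSV, a
    population map, mito counts and all truth tables there.
    """
    freqs, truth = simulate_allele_frequencies(config)
    counts, truth = simulate_reads(freqs, config, truth)
    mito_counts, hap_table, true_seqs = simulate_mito_alignment(config)
    truth.mito_haplotypes = hap_table
    truth.mito_sequences = true_seqs

    individuals = config.individuals()
    major_idx = truth.sites["major"].map(
        {b: i for i, b in enumerate(BASES)}
    ).to_numpy()
    minor_idx = truth.sites["minor"].map(
        {b: i for i, b in enumerate(BASES)}
    ).to_numpy()
    gls = gl_from_counts(counts, major_idx, minor_idx, config.error_rate)
    gl = GLMatrix(
        truth.sites[["chrom", "pos", "major", "minor"]].copy(), individuals, gls
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_beagle(gl, outdir / "genolike.beagle.tsv")
        write_counts_tsv(truth.sites, individuals, counts, outdir / "counts.tsv")
        individuals.to_csv(outdir / "popmap.tsv", sep="\t", index=False,
                           lineterminator="\n")
        _write_mito_counts(mito_counts, individuals, outdir / "mito_counts.tsv")
        truth.write(outdir / "truth", individuals)
    return gl, mito_counts, truth


def _write_mito_counts(
    counts: np.ndarray, individuals: pd.DataFrame, path: str | Path
) -> None:
    """Long-format mito counts: individual, pos (1-based), A, C, G, T."""
    N, L, _ = counts.shape
    rec = pd.DataFrame(
        {
            "individual": np.repeat(individuals["id"].to_numpy(), L),
            "pos": np.tile(np.arange(1, L + 1), N),
            "A": counts[:, :, 0].ravel(),
            "C": counts[:, :, 1].ravel(),
            "G": counts[:, :, 2].ravel(),
            "T": counts[:, :, 3].ravel(),
        }
    )
    rec.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_mito_counts(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Inverse of the mito counts writer; returns (individuals, (N, L, 4))."""
    df = pd.read_csv(path, sep="\t")
    ids = pd.unique(df["individual"])
    L = df["pos"].max()
    counts = df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64).reshape(
        len(ids), int(L), 4
    )
    return pd.DataFrame({"id": ids}), counts
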