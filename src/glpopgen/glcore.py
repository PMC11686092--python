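"""Genotype likelihoods from base calls, and the pipeline's core matrix formats.

The per-read error model is the standard one for low-coverage data: a read
carrying base ``b`` has probability ``1 - eps`` of being correct under a true
allele ``a == b`` and ``eps / 3`` of being any specific other base.  Under a
diploid genotype the two alleles are sampled with equal probability, so

    P(b | g = a1/a2) = (P(b | a1) + P(b | a2)) / 2

and the site likelihood is the product over reads.  Likelihoods are restricted
to the three genotypes over the site's two alleles (hom-major, het, hom-minor)
and normalized to sum to one; an individual with zero overlapping reads gets
the uninformative triple (1/3, 1/3, 1/3).

File formats follow the Beagle genotype-likelihood convention: a tab-separated
text file with a ``marker`` column (``chrom_pos``), two numeric allele codes
(0=A, 1=C, 2=G, 3=T) and three likelihood columns per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_TOL = 1e-3  # |GL - 1/3| below this on all entries counts as "no data"

__all__ = [
    "BASES",
    "BASE_INDEX",
    "GLMatrix",
    "genotype_likelihood",
    "gl_from_counts",
    "read_beagle",
    "write_beagle",
    "read_counts_tsv",
    "write_counts_tsv",
]


def _allele_probs(eps: np.ndarray | float) -> np.ndarray:
    """P(read base | true allele) as a (..., 4, 4) matrix (allele, base)."""
    eps = np.asarray(eps, dtype=float)
    out = np.full(eps.shape + (4, 4), 0.0)
    out[...] = (eps / 3.0)[..., None, None]
    idx = np.arange(4)
    out[..., idx, idx] = (1.0 - eps)[..., None]
    return out


def genotype_likelihood(
    base_calls: Iterable[tuple[str, float]], major: str, minor: str
) -> np.ndarray:
    """Normalized GL triple (hom-major, het, hom-minor) for one individual.

    Parameters
    ----------
    base_calls
        Iterable of ``(base, error_prob)`` per overlapping read.
    major, minor
        The site's two alleles (single characters in ``ACGT``).

    Returns
    -------
    ndarray of shape (3,) summing to 1.  Zero reads yields (1/3, 1/3, 1/3).
    """
    if major == minor:
        raise ValueError("major and minor allele must differ")
    M, m = BASE_INDEX[major], BASE_INDEX[minor]
    loglik = np.zeros(3)
    n = 0
    for base, eps in base_calls:
        if not 0.0 <= eps < 0.75:
            raise ValueError(f"error probability {eps} outside [0, 0.75)")
        b = BASE_INDEX[base]
        p_M = 1.0 - eps if b == M else eps / 3.0
        p_m = 1.0 - eps if b == m else eps / 3.0
        per_g = np.array([p_M, 0.5 * (p_M + p_m), p_m])
        with np.errstate(divide="ignore"):
            loglik += np.log(per_g)
        n += 1
    if n == 0:
        return np.full(3, 1.0 / 3.0)
    lik = np.exp(loglik - loglik.max())
    return lik / lik.sum()


def gl_from_counts(
    counts: np.ndarray,
    major_idx: np.ndarray,
    minor_idx: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Vectorized GL computation from 4-base read counts.

    Parameters
    ----------
    counts : (S, N, 4) int array of A/C/G/T read counts.
    major_idx, minor_idx : (S,) allele indices into ACGT.
    error_rate : per-base error probability shared by all reads.

    Returns
    -------
    (S, N, 3) normalized likelihood triples; zero-depth entries are uniform.
    """
    counts = np.asarray(counts, dtype=float)
    S = counts.shape[0]
    probs = _allele_probs(error_rate)  # (4, 4)
    p_major = probs[major_idx]  # (S, 4): P(base | major allele)
    p_minor = probs[minor_idx]
    per_g = np.stack([p_major, 0.5 * (p_major + p_minor), p_minor], axis=1)  # (S,3,4)
    with np.errstate(divide="ignore"):
        log_per_g = np.log(per_g)
    log_per_g[np.isneginf(log_per_g)] = -745.0  # exp() underflows cleanly
    loglik = np.einsum("snb,sgb->sng", counts, log_per_g)  # (S, N, 3)
    loglik -= loglik.max(axis=2, keepdims=True)
    lik = np.exp(loglik)
    lik /= lik.sum(axis=2, keepdims=True)
    return lik


@dataclass
class GLMatrix:
    """Sites x individuals x 3 normalized genotype likelihoods.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), major, minor.
    individuals : DataFrame with columns id, pop.
    gls : (S, N, 3) array; each triple sums to 1.
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame
    gls: np.ndarray

    def __post_init__(self) -> None:
        self.gls = np.asarray(self.gls, dtype=float)
        if self.gls.shape != (len(self.sites), len(self.individuals), 3):
            raise ValueError("gls shape does not match sites/individuals")
        sums = self.gls.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("GL triples must be normalized to sum to 1")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing_mask(self) -> np.ndarray:
        """(S, N) boolean: True where the triple is uniform (no data)."""
        return np.all(np.abs(self.gls - 1.0 / 3.0) < UNIFORM_TOL, axis=2)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Column indices per population label, in file order."""
        pops = self.individuals["pop"].to_numpy()
        return {p: np.flatnonzero(pops == p) for p in pd.unique(pops)}

    def subset_sites(self, mask: np.ndarray) -> "GLMatrix":
        mask = np.asarray(mask)
        return GLMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.individuals,
            self.gls[mask],
        )

    def subset_individuals(self, idx: Sequence[int]) -> "GLMatrix":
        idx = np.asarray(idx)
        return GLMatrix(
            self.sites,
            self.individuals.iloc[idx].reset_index(drop=True),
            self.gls[:, idx],
        )


def write_beagle(gl: GLMatrix, path: str | Path, precision: int = 6) -> None:
    """Write a Beagle-GL text file (three likelihood columns per individual)."""
    path = Path(path)
    S, N = gl.n_sites, gl.n_individuals
    ids = gl.individuals["id"].tolist()
    header = ["marker", "allele1", "allele2"]
    for i in ids:
        header += [str(i)] * 3
    chrom = gl.sites["chrom"].astype(str).to_numpy()
    pos = gl.sites["pos"].to_numpy()
    a1 = gl.sites["major"].map(BASE_INDEX).to_numpy()
    a2 = gl.sites["minor"].map(BASE_INDEX).to_numpy()
    flat = gl.gls.reshape(S, 3 * N)
    fmt = f"%.{precision}f"
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for s in range(S):
            row = [f"{chrom[s]}_{pos[s]}", str(a1[s]), str(a2[s])]
            row += [fmt % v for v in flat[s]]
            fh.write("\t".join(row) + "\n")


def read_beagle(
    path: str | Path, individuals: pd.DataFrame | None = None
) -> GLMatrix:
    """Read a Beagle-GL file back into a :class:`GLMatrix`.

    ``individuals`` supplies population labels; if omitted, the ids from the
    header are used with population "unknown".
    """
    df = pd.read_csv(path, sep="\t")
    marker = df["marker"].astype(str)
    chrom = marker.str.rsplit("_", n=1).str[0]
    pos = marker.str.rsplit("_", n=1).str[1].astype(int)
    major = df["allele1"].astype(int).map(lambda i: BASES[i])
    minor = df["allele2"].astype(int).map(lambda i: BASES[i])
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "major": major, "minor": minor}
    ).reset_index(drop=True)
    vals = df.iloc[:, 3:].to_numpy(dtype=float)
    N = vals.shape[1] // 3
    gls = vals.reshape(len(df), N, 3)
    gls = gls / gls.sum(axis=2, keepdims=True)
    if individuals is None:
        ids = [df.columns[3 + 3 * i] for i in range(N)]
        individuals = pd.DataFrame({"id": ids, "pop": ["unknown"] * N})
    return GLMatrix(sites, individuals.reset_index(drop=True), gls)


def write_counts_tsv(
    sites: pd.DataFrame,
    individuals: pd.DataFrame,
    counts: np.ndarray,
    path: str | Path,
) -> None:
    """Long-format per-site per-individual base counts (chrom, pos, id, A,C,G,T)."""
    S, N, _ = counts.shape
    rec = pd.DataFrame(
        {
            "chrom": np.repeat(sites["chrom"].to_numpy(), N),
            "pos": np.repeat(sites["pos"].to_numpy(), N),
            "individual": np.tile(individuals["id"].to_numpy(), S),
            "A": counts[:, :, 0].ravel(),
            "C": counts[:, :, 1].ravel(),
            "G": counts[:, :, 2].ravel(),
            "T": counts[:, :, 3].ravel(),
        }
    )
    rec.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Inverse of :func:`write_counts_tsv`.

    Returns (sites, individuals, counts) with counts of shape (S, N, 4);
    population labels are not stored in the counts file and come back as
    "unknown".
    """
    df = pd.read_csv(path, sep="\t")
    ids = pd.unique(df["individual"])
    site_keys = df[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    S, N = len(site_keys), len(ids)
    counts = df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64).reshape(S, N, 4)
    individuals = pd.DataFrame({"id": ids, "pop": ["unknown"] * N})
    return site_keys, individuals, counts
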