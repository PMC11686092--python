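"""Hudson FST per site and weighted across sites for all population pairs.

The per-site Hudson estimator for allele frequencies p1, p2 estimated from
n1, n2 sampled chromosomes is

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

and the multi-site (weighted) estimate is the ratio of sums sum(num)/sum(den)
- never an average of per-site ratios, whose expectation is badly biased.
Negative per-site numerators are retained in the sums.  The estimator is
robust to unequal sample sizes, which is why it suits designs with very
different per-region sample counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import estimate_maf_em
from .glcore import GLMatrix

__all__ = ["hudson_site", "pairwise_fst", "weighted_fst"]


def hudson_site(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator (vectorized).

    ``n1, n2`` are allele (chromosome) counts and must be >= 2.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("allele counts must be >= 2 in both populations")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def weighted_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-sums FST; sites with zero denominator are skipped."""
    keep = np.asarray(den) > 0
    d = float(np.sum(np.asarray(den)[keep]))
    if d == 0.0:
        return float("nan")
    return float(np.sum(np.asarray(num)[keep]) / d)


def pairwise_fst(
    gl: GLMatrix, min_individuals: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted Hudson FST for every population pair, plus per-site tracks.

    Allele frequencies come from per-population EM on the GLs under the
    shared (global) major/minor polarization; the chromosome count at a site
    is twice the number of individuals with any data.  A site enters a pair's
    sums only if both populations have >= ``min_individuals`` individuals
    with data and the denominator is positive.

    Returns
    -------
    (matrix, track): a long-format symmetric matrix DataFrame
    (pop1, pop2, fst) and a per-site DataFrame with num/den/ratio per pair.
    """
    pops = gl.pop_indices()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    present = ~gl.missing_mask()  # (S, N)
    freqs: dict[str, np.ndarray] = {}
    n_chr: dict[str, np.ndarray] = {}
    for name, idx in pops.items():
        f, _ = estimate_maf_em(gl.gls[:, idx])
        freqs[name] = f
        n_chr[name] = 2 * present[:, idx].sum(axis=1)
    names = list(pops)
    rows = []
    track_cols: dict[str, np.ndarray] = {
        "chrom": gl.sites["chrom"].to_numpy(),
        "pos": gl.sites["pos"].to_numpy(),
    }
    track = pd.DataFrame(track_cols)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ok = (
                (n_chr[a] >= 2 * min_individuals)
                & (n_chr[b] >= 2 * min_individuals)
                & np.isfinite(freqs[a])
                & np.isfinite(freqs[b])
            )
            num = np.full(gl.n_sites, np.nan)
            den = np.full(gl.n_sites, np.nan)
            num[ok], den[ok] = hudson_site(
                freqs[a][ok], n_chr[a][ok], freqs[b][ok], n_chr[b][ok]
            )
            usable = ok & (den > 0)
            fst = weighted_fst(num[usable], den[usable])
            rows.append({"pop1": a, "pop2": b, "fst": fst})
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(den > 0, num / den, np.nan)
            track[f"num_{a}_{b}"] = num
            track[f"den_{a}_{b}"] = den
            track[f"fst_{a}_{b}"] = ratio
    return pd.DataFrame(rows), track
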