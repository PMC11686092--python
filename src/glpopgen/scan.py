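"""Selection scan: per-SNP Fisher exact tests and local-score aggregation.

Each SNP contributes a score s_i = -log10(p_i) - xi, where p_i is the
two-sided Fisher exact test p-value comparing allele counts between two
populations and xi (default 2) tunes how much clustering of moderately
significant SNPs is rewarded.  The Lindley process

    h_0 = 0,   h_i = max(0, h_{i-1} + s_i)

accumulates runs of positive scores; with xi > 1 the mean score under the
null is negative, so h returns to zero between signal clusters.  A
per-chromosome significance threshold at level alpha is an upper order
statistic of the maximum Lindley value over seeded permutations of that
chromosome's scores (a Gumbel fit to the permuted maxima is the fast
alternative); a chromosome is significant when its observed maximum strictly
exceeds the threshold.  Outlier regions are maximal h > 0 runs containing a
threshold exceedance, reported from their first to last SNP position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng

__all__ = [
    "fet_pair",
    "fet_table",
    "lindley",
    "permutation_threshold",
    "local_score_scan",
    "ScanResult",
    "pop_allele_counts",
]

P_FLOOR = 1e-300  # floor before log10 so scores stay finite
MIN_SNPS_PER_CHROM = 10


def fet_pair(table: np.ndarray) -> float:
    """Two-sided Fisher exact test p-value for one 2x2 count table.

    Exact hypergeometric enumeration: the p-value sums the probabilities of
    all tables (with the observed margins) no more probable than the observed
    one.  A zero margin gives p = 1.
    """
    return float(fet_table(np.asarray(table, dtype=np.int64)[None])[0])


def fet_table(tables: np.ndarray) -> np.ndarray:
    """Vectorized two-sided FET over (T, 2, 2) integer tables."""
    tables = np.asarray(tables, dtype=np.int64)
    if tables.ndim == 2:
        tables = tables[None]
    if np.any(tables < 0):
        raise ValueError("counts must be non-negative")
    a = tables[:, 0, 0]
    r1 = tables[:, 0, 0] + tables[:, 0, 1]
    c1 = tables[:, 0, 0] + tables[:, 1, 0]
    n = tables.sum(axis=(1, 2))
    out = np.ones(len(tables))
    for t in range(len(tables)):
        if r1[t] == 0 or c1[t] == 0 or r1[t] == n[t] or c1[t] == n[t]:
            continue  # a zero margin fixes the table: p = 1
        lo = max(0, r1[t] + c1[t] - n[t])
        hi = min(r1[t], c1[t])
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, n[t], c1[t], r1[t])
        p_obs = pmf[a[t] - lo]
        out[t] = pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()
    return np.minimum(out, 1.0)


def pop_allele_counts(
    counts: np.ndarray,
    major_idx: np.ndarray,
    minor_idx: np.ndarray,
    pop_columns: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Read-backed (major, minor) allele counts per population.

    Sums base counts over a population's individuals, keeping only reads
    carrying one of the site's two alleles - this mirrors per-region count
    dumps that have no individual resolution.  Returns per population an
    (S, 2) array.
    """
    S = counts.shape[0]
    rows = np.arange(S)
    out = {}
    for name, idx in pop_columns.items():
        summed = counts[:, idx, :].sum(axis=1)  # (S, 4)
        out[name] = np.stack(
            [summed[rows, major_idx], summed[rows, minor_idx]], axis=1
        )
    return out


def lindley(scores: np.ndarray) -> np.ndarray:
    """Lindley process h_i = max(0, h_{i-1} + s_i), h_0 = 0 before the data."""
    scores = np.asarray(scores, dtype=float)
    h = np.empty_like(scores)
    acc = 0.0
    for i, s in enumerate(scores):
        acc = max(0.0, acc + s)
        h[i] = acc
    return h


def _max_lindley_batch(score_matrix: np.ndarray) -> np.ndarray:
    """Maximum Lindley value for each row of a (R, L) score matrix."""
    R, L = score_matrix.shape
    h = np.zeros(R)
    mx = np.zeros(R)
    for i in range(L):
        h = np.maximum(0.0, h + score_matrix[:, i])
        np.maximum(mx, h, out=mx)
    return mx


def permutation_threshold(
    scores: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> float:
    """Per-chromosome significance threshold for the maximum Lindley value.

    ``method='permutation'`` takes the empirical (1 - alpha) quantile of the
    max-Lindley over ``n_perm`` random reorderings of the scores, using the
    permutation-test order statistic: the k-th largest permuted maximum with
    k = floor(alpha * (n_perm + 1)).  An observed maximum STRICTLY above this
    threshold has permutation p-value (1 + #{perm >= obs})/(n_perm + 1) below
    alpha even in the presence of ties, which the max-Lindley distribution
    has in abundance (the maximum usually equals the largest single score,
    whatever the ordering).  ``method='gumbel'`` fits a Gumbel law to those
    maxima and returns its (1 - alpha) quantile.
    """
    rng = stage_rng(seed, "local_score_threshold")
    scores = np.asarray(scores, dtype=float)
    perms = rng.permuted(
        np.broadcast_to(scores, (n_perm, len(scores))).copy(), axis=1
    )
    maxima = _max_lindley_batch(perms)
    if method == "permutation":
        k = max(1, int(alpha * (n_perm + 1)))
        return float(np.sort(maxima)[n_perm - k])
    if method == "gumbel":
        loc, scale = stats.gumbel_r.fit(maxima)
        return float(stats.gumbel_r.ppf(1.0 - alpha, loc, scale))
    raise ValueError(f"unknown threshold method {method!r}")


@dataclass
class ScanResult:
    """Local-score scan output for one population pair."""

    snps: pd.DataFrame  # chrom, pos, p, score, lindley
    thresholds: pd.DataFrame  # chrom, threshold, alpha, method
    regions: pd.DataFrame  # chrom, start, end, peak, n_snps
    xi: float = 2.0
    alpha: float = 0.01
    skipped_chroms: list[str] = field(default_factory=list)


def local_score_scan(
    chrom: np.ndarray,
    pos: np.ndarray,
    pvals: np.ndarray,
    xi: float = 2.0,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    threshold_method: str = "permutation",
) -> ScanResult:
    """Run the local-score scan over position-sorted SNP p-values.

    Chromosomes with fewer than 10 SNPs are skipped.  Region bounds run from
    the first to the last SNP of the maximal h > 0 run containing an
    exceedance (zero-crossing to zero-crossing), 1-based inclusive.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    pvals = np.asarray(pvals, dtype=float)
    scores = -np.log10(np.maximum(pvals, P_FLOOR)) - xi
    snp_rows = []
    thr_rows = []
    region_rows = []
    skipped = []
    for c in pd.unique(chrom):
        m = chrom == c
        p_c = pos[m]
        if np.any(np.diff(p_c) < 0):
            raise ValueError(f"positions not sorted within chromosome {c}")
        s_c = scores[m]
        if len(s_c) < MIN_SNPS_PER_CHROM:
            skipped.append(str(c))
            continue
        h = lindley(s_c)
        thr = permutation_threshold(
            s_c, alpha=alpha, n_perm=n_perm, seed=seed, method=threshold_method
        )
        snp_rows.append(
            pd.DataFrame(
                {"chrom": c, "pos": p_c, "p": pvals[m], "score": s_c, "lindley": h}
            )
        )
        thr_rows.append(
            {"chrom": c, "threshold": thr, "alpha": alpha,
             "method": threshold_method}
        )
        # Maximal h > 0 runs; report those whose peak reaches the threshold.
        positive = h > 0
        if positive.any():
            edges = np.diff(positive.astype(int))
            starts = list(np.flatnonzero(edges == 1) + 1)
            ends = list(np.flatnonzero(edges == -1))
            if positive[0]:
                starts = [0] + starts
            if positive[-1]:
                ends = ends + [len(h) - 1]
            for s0, e0 in zip(starts, ends):
                peak = h[s0 : e0 + 1].max()
                if peak > thr:
                    region_rows.append(
                        {
                            "chrom": c,
                            "start": int(p_c[s0]),
                            "end": int(p_c[e0]),
                            "peak": float(peak),
                            "n_snps": int(e0 - s0 + 1),
                        }
                    )
    snps = (
        pd.concat(snp_rows, ignore_index=True)
        if snp_rows
        else pd.DataFrame(columns=["chrom", "pos", "p", "score", "lindley"])
    )
    return ScanResult(
        snps=snps,
        thresholds=pd.DataFrame(thr_rows, columns=["chrom", "threshold",
                                                   "alpha", "method"]),
        regions=pd.DataFrame(
            region_rows, columns=["chrom", "start", "end", "peak", "n_snps"]
        ),
        xi=xi,
        alpha=alpha,
        skipped_chroms=skipped,
    )
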