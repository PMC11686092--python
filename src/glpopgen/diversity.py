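"""Folded site-frequency spectra, diversity statistics and inbreeding.

The sample-allele-frequency (SAF) likelihood P(data_s | j) for j minor-allele
copies among 2N sampled chromosomes is built by dynamic programming over
individuals: each diploid contributes g in {0,1,2} copies with weight
GL_g * C(2,g), and the convolution over individuals divided by C(2N, j) gives
the likelihood of each total count under uniform assignment of copies.  With
known genotypes this is a point mass at the true count.

The folded spectrum eta_j (j = 0..N) is the EM maximizer of
sum_s log sum_j eta_j P(data_s | j); per-site posteriors under that global
spectrum as a prior yield Watterson's theta and pi per site, summed over
sliding windows, with Tajima's D from the standard (1989) constants.

Per-individual inbreeding F in [0, 1] is estimated by EM on the mixture
reading of  P(g | f, F) = F * IBD(g | f) + (1 - F) * HWE(g | f),
with IBD(g | f) = (1 - f, 0, f).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "saf_likelihoods",
    "saf_site",
    "fold_saf",
    "sfs_em",
    "tajima_constants",
    "site_stats",
    "window_thetas",
    "inbreeding_em",
    "compare_window_means",
]


def saf_likelihoods(gls: np.ndarray) -> np.ndarray:
    """Unfolded SAF likelihood matrix P(data | j), shape (S, 2N+1).

    Max-normalized per site; exact (a point mass) for degenerate GLs.
    """
    gls = np.asarray(gls, dtype=float)
    S, N, _ = gls.shape
    J = 2 * N + 1
    v = np.zeros((S, J))
    v[:, 0] = 1.0
    width = 1  # current support is 0..width-1
    for i in range(N):
        w0 = gls[:, i, 0][:, None]
        w1 = (2.0 * gls[:, i, 1])[:, None]
        w2 = gls[:, i, 2][:, None]
        nxt = np.zeros_like(v)
        nxt[:, : width] = v[:, : width] * w0
        nxt[:, 1 : width + 1] += v[:, : width] * w1
        nxt[:, 2 : width + 2] += v[:, : width] * w2
        width += 2
        mx = nxt.max(axis=1, keepdims=True)
        v = nxt / np.maximum(mx, 1e-300)
    binom = np.array([comb(2 * N, j) for j in range(J)], dtype=float)
    v = v / binom
    v /= np.maximum(v.max(axis=1, keepdims=True), 1e-300)
    return v


def saf_site(gl_column: np.ndarray) -> np.ndarray:
    """Folded SAF vector (length N+1) for a single site, max-normalized."""
    saf = saf_likelihoods(np.asarray(gl_column)[None])
    return fold_saf(saf)[0]


def fold_saf(saf: np.ndarray) -> np.ndarray:
    """Fold an unfolded (S, 2N+1) SAF matrix to minor counts 0..N."""
    S, J = saf.shape
    N = (J - 1) // 2
    folded = np.empty((S, N + 1))
    for j in range(N):
        folded[:, j] = saf[:, j] + saf[:, 2 * N - j]
    folded[:, N] = saf[:, N]
    return folded / np.maximum(folded.max(axis=1, keepdims=True), 1e-300)


def sfs_em(
    saf: np.ndarray, tol: float = 1e-6, max_iter: int = 1000
) -> np.ndarray:
    """EM estimate of the spectrum eta (counts scale: sums to n_sites)."""
    saf = np.asarray(saf, dtype=float)
    S, J = saf.shape
    if S < 1:
        raise ValueError("need at least one site")
    eta = np.full(J, 1.0 / J)
    ll_old = -np.inf
    for _ in range(max_iter):
        w = saf * eta  # (S, J)
        tot = w.sum(axis=1)
        ll = float(np.log(np.maximum(tot, 1e-300)).sum())
        post = w / np.maximum(tot, 1e-300)[:, None]
        eta = post.mean(axis=0)
        if ll - ll_old < tol and np.isfinite(ll_old):
            break
        ll_old = ll
    return eta * S


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled sequences."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_stats(
    saf_folded: np.ndarray, sfs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (pi, P(segregating)) posteriors under the global SFS prior.

    pi_s is the expected heterozygosity j(2N-j)/C(2N,2) under the posterior
    over folded counts; theta_W per site is P(segregating)/a1.
    """
    saf_folded = np.asarray(saf_folded, dtype=float)
    sfs = np.asarray(sfs, dtype=float)
    S, J = saf_folded.shape
    N = J - 1
    n_chr = 2 * N
    w = saf_folded * sfs
    post = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
    j = np.arange(J)
    pi_weight = j * (n_chr - j) / comb(n_chr, 2)
    pi = post @ pi_weight
    p_seg = 1.0 - post[:, 0]
    return pi, p_seg


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_sites: int
    theta_w: float
    pi: float
    tajima_d: float  # nan when undefined
    partial: bool = False


def window_thetas(
    saf_folded: np.ndarray,
    sfs: np.ndarray,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = 5000,
    step: int = 1000,
) -> pd.DataFrame:
    """Sliding-window theta_W, pi and Tajima's D.

    Windows are 1-based inclusive, anchored at position 1, advancing by
    ``step``; the final partial window is retained and flagged.  D is left nan
    where the windowed expected number of segregating sites is ~0.
    """
    pi_s, p_seg = site_stats(saf_folded, sfs)
    N = saf_folded.shape[1] - 1
    const = tajima_constants(2 * N)
    a1 = const["a1"]
    rows: list[WindowStat] = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None and chrom in chrom_lengths
            else int(pos.max())
        )
        start = 1
        while start <= length:
            end = min(start + window_size - 1, length)
            in_win = (pos >= start) & (pos <= end)
            sel = idx[in_win]
            n_sites = len(sel)
            S_star = float(p_seg[sel].sum())
            pi_star = float(pi_s[sel].sum())
            theta_w = S_star / a1
            if S_star > 1e-8:
                var = const["e1"] * S_star + const["e2"] * S_star * (S_star - 1)
                d = (pi_star - theta_w) / np.sqrt(var) if var > 0 else np.nan
            else:
                d = np.nan
            rows.append(
                WindowStat(str(chrom), start, end, n_sites, theta_w, pi_star,
                           d, partial=(end - start + 1 < window_size))
            )
            if end >= length:
                break
            start += step
    return pd.DataFrame([r.__dict__ for r in rows])


def inbreeding_em(
    gls: np.ndarray,
    freqs: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_sites: int = 50,
) -> pd.DataFrame:
    """Per-individual inbreeding coefficient F in [0, 1] by EM.

    Parameters
    ----------
    gls : (S, N, 3) likelihoods at polymorphic sites only.
    freqs : (S,) allele frequencies (minor, matching the GL orientation).

    Returns a DataFrame (F_hat, n_informative, low_confidence).
    """
    gls = np.asarray(gls, dtype=float)
    f = np.asarray(freqs, dtype=float)
    keep = np.isfinite(f) & (f > 0.0) & (f < 1.0)
    gls = gls[keep]
    f = f[keep]
    S, N, _ = gls.shape
    hwe = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
    ibd = np.stack([1 - f, np.zeros_like(f), f], axis=-1)
    lik_hwe = np.einsum("sng,sg->sn", gls, hwe)  # (S, N)
    lik_ibd = np.einsum("sng,sg->sn", gls, ibd)
    F = np.full(N, 0.01)
    for _ in range(max_iter):
        num = F[None, :] * lik_ibd
        den = num + (1.0 - F[None, :]) * lik_hwe
        z = num / np.maximum(den, 1e-300)
        F_new = z.mean(axis=0)
        if np.max(np.abs(F_new - F)) < tol:
            F = F_new
            break
        F = F_new
    informative = np.any(np.abs(gls - 1.0 / 3.0) >= 1e-3, axis=2).sum(axis=0)
    return pd.DataFrame(
        {
            "F_hat": F,
            "n_informative": informative,
            "low_confidence": informative < min_sites,
        }
    )


def compare_window_means(
    stats_a: np.ndarray, stats_b: np.ndarray, equal_var: bool = True,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Two-sample t test on window statistics (outlier vs background).

    Pooled-variance by default (Welch via ``equal_var=False``).  Returns the
    mean difference (a - b), t, two-tailed p, degrees of freedom and the
    (1 - alpha) CI of the difference.  Overlapping sliding windows are
    autocorrelated, so the nominal p-value is anti-conservative; callers
    should read it as approximate.
    """
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two windows")
    diff = a.mean() - b.mean()
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return {"mean_diff": float(diff), "t": 0.0 if diff == 0 else np.inf,
                "p": 1.0 if diff == 0 else 0.0, "df": len(a) + len(b) - 2,
                "ci_low": float(diff), "ci_high": float(diff)}
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        se = np.sqrt(va + vb)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return {
        "mean_diff": float(diff),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": float(df),
        "ci_low": float(diff - tcrit * se),
        "ci_high": float(diff + tcrit * se),
    }
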