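"""Population structure from genotype likelihoods: PCA, admixture, model choice.

PCA operates on the covariance of posterior-mean genotypes: with the HWE
prior at the site's EM allele frequency fhat_s, each individual's expected
minor-allele dosage e_is is standardized as (e_is - 2 f_s)/sqrt(2 f_s (1-f_s))
and the individual-by-individual covariance matrix is averaged over sites.

Admixture proportions are estimated NGSadmix-style: maximize

    prod_i prod_s sum_g GL_isg Binom(g; 2, pi_is),   pi_is = sum_k Q_ik F_sk

by EM on expected allele-copy counts, with random restarts; model choice
across K uses AICc with p = N(K-1) + S*K free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .filters import estimate_maf_em
from .glcore import GLMatrix

__all__ = [
    "CovarianceResult",
    "AdmixtureResult",
    "covariance_pca",
    "balanced_subsample",
    "admixture_em",
    "aicc_select",
]


@dataclass
class CovarianceResult:
    cov: np.ndarray  # (N, N)
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns match eigenvalues
    pct_variance: np.ndarray  # over all PCs, sums to 100
    individuals: pd.DataFrame

    def coordinates(self, k: int = 2) -> pd.DataFrame:
        """Individual PC coordinates scaled by sqrt(eigenvalue)."""
        lam = np.clip(self.eigenvalues[:k], 0.0, None)
        coords = self.eigenvectors[:, :k] * np.sqrt(lam)
        df = self.individuals.copy()
        for j in range(k):
            df[f"PC{j + 1}"] = coords[:, j]
        return df


def posterior_mean_genotypes(
    gls: np.ndarray, f: np.ndarray
) -> np.ndarray:
    """(S, N) expected minor-allele dosage under the HWE prior at f."""
    f = np.asarray(f, dtype=float)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
    w = gls * prior[:, None, :]
    w /= w.sum(axis=2, keepdims=True)
    return w[:, :, 1] + 2.0 * w[:, :, 2]


def covariance_pca(
    gl: GLMatrix,
    freqs: np.ndarray | None = None,
    min_maf: float = 1e-4,
) -> CovarianceResult:
    """Genotype-likelihood PCA across individuals.

    Sites with an estimated frequency within ``min_maf`` of fixation are
    skipped (their standardization denominator vanishes).
    """
    if gl.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    if freqs is None:
        freqs, _ = estimate_maf_em(gl.gls)
    freqs = np.asarray(freqs, dtype=float)
    keep = np.isfinite(freqs) & (freqs > min_maf) & (freqs < 1.0 - min_maf)
    f = freqs[keep]
    e = posterior_mean_genotypes(gl.gls[keep], f)
    X = (e - 2.0 * f[:, None]) / np.sqrt(2.0 * f * (1.0 - f))[:, None]
    S = X.shape[0]
    if S == 0:
        raise ValueError("no polymorphic sites available for PCA")
    C = X.T @ X / S
    C = (C + C.T) / 2.0
    lam, vec = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pct = 100.0 * lam / lam.sum()
    return CovarianceResult(C, lam, vec, pct, gl.individuals.copy())


def balanced_subsample(
    individuals: pd.DataFrame, max_per_pop: int = 16, seed: int = 0
) -> np.ndarray:
    """Indices downsampling every population with N > max_per_pop to max_per_pop.

    Mirrors the region-balancing used before PCA so that unequal sample sizes
    do not distort PC space.
    """
    rng = stage_rng(seed, "pca_subsample")
    keep: list[int] = []
    pops = individuals["pop"].to_numpy()
    for p in pd.unique(pops):
        idx = np.flatnonzero(pops == p)
        if len(idx) > max_per_pop:
            idx = np.sort(rng.choice(idx, size=max_per_pop, replace=False))
        keep.extend(idx.tolist())
    return np.array(sorted(keep))


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (N, K) ancestry proportions, rows sum to 1
    F: np.ndarray  # (S, K) cluster allele frequencies
    loglik: float
    K: int
    seed: int
    converged: bool
    n_iter: int
    loglik_path: np.ndarray | None = None


def _admixture_loglik(gls: np.ndarray, pi: np.ndarray) -> float:
    prior = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)
    marg = np.einsum("sng,sng->sn", gls, prior)
    return float(np.log(np.maximum(marg, 1e-300)).sum())


def _admixture_fit(
    gls: np.ndarray, K: int, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> AdmixtureResult:
    S, N, _ = gls.shape
    eps = 1e-6
    if K == 1:
        F, _ = estimate_maf_em(gls)
        F = np.clip(np.nan_to_num(F, nan=0.0), eps, 1 - eps)[:, None]
        Q = np.ones((N, 1))
        ll = _admixture_loglik(gls, (F @ Q.T))
        return AdmixtureResult(Q, F, ll, 1, 0, True, 0)
    Q = rng.dirichlet(np.ones(K), size=N)  # (N, K)
    F = rng.uniform(0.05, 0.95, size=(S, K))
    ll_old = -np.inf
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = np.clip(F @ Q.T, eps, 1 - eps)  # (S, N)
        prior = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)
        w = gls * prior
        marg = w.sum(axis=2)  # (S, N)
        ll = float(np.log(np.maximum(marg, 1e-300)).sum())
        path.append(ll)
        post = w / np.maximum(marg, 1e-300)[:, :, None]
        eg = post[:, :, 1] + 2.0 * post[:, :, 2]  # expected minor copies (S, N)
        rm = eg / pi  # minor-copy responsibility scale
        rM = (2.0 - eg) / (1.0 - pi)
        minor_sk = F * (rm @ Q)  # (S, K) expected minor copies to cluster k
        major_sk = (1.0 - F) * (rM @ Q)
        # Both updates use the E-step quantities from the same (F, Q) iterate.
        n_ik = Q * (rm.T @ F + rM.T @ (1.0 - F))
        F = np.clip(minor_sk / np.maximum(minor_sk + major_sk, 1e-300), eps, 1 - eps)
        Q = np.clip(n_ik / (2.0 * S), eps, None)
        Q /= Q.sum(axis=1, keepdims=True)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    pi = np.clip(F @ Q.T, eps, 1 - eps)
    ll = _admixture_loglik(gls, pi)
    return AdmixtureResult(Q, F, ll, K, 0, converged, it,
                           loglik_path=np.asarray(path))


def admixture_em(
    gl: GLMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-5,
    max_iter: int = 2000,
    polymorphic_only: bool = True,
) -> AdmixtureResult:
    """Estimate admixture proportions for K ancestral clusters.

    Runs ``n_restarts`` EM fits from random starts (restart r uses seed
    ``seed + r``) and returns the best by log-likelihood.  Only polymorphic
    sites are used (no MAF floor beyond polymorphism).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    gls = gl.gls if isinstance(gl, GLMatrix) else np.asarray(gl)
    if polymorphic_only:
        f, _ = estimate_maf_em(gls)
        keep = np.isfinite(f) & (f > 1e-6) & (f < 1.0 - 1e-6)
        gls = gls[keep]
    best: AdmixtureResult | None = None
    n_fits = 1 if K == 1 else n_restarts
    for r in range(n_fits):
        rng = stage_rng(seed + r, f"admixture_K{K}")
        fit = _admixture_fit(gls, K, rng, tol, max_iter)
        fit.seed = seed + r
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def aicc_select(fits: dict[int, AdmixtureResult], n_individuals: int,
                n_sites: int) -> pd.DataFrame:
    """AICc table across K and the selected model.

    p = N(K-1) + S*K free parameters, n = N*S observations;
    AICc = -2 lnL + 2p + 2p(p+1)/(n - p - 1), falling back to AIC when the
    correction denominator is non-positive.

    Returns a DataFrame (K, loglik, n_params, aicc, used_aic, best).
    """
    if not fits:
        raise ValueError("no fits supplied")
    N, S = n_individuals, n_sites
    n_obs = N * S
    rows = []
    for K in sorted(fits):
        fit = fits[K]
        p = N * (K - 1) + S * K
        aic = -2.0 * fit.loglik + 2.0 * p
        if n_obs - p - 1 > 0:
            crit = aic + 2.0 * p * (p + 1) / (n_obs - p - 1)
            used_aic = False
        else:
            crit = aic
            used_aic = True
        rows.append({"K": K, "loglik": fit.loglik, "n_params": p,
                     "aicc": crit, "used_aic": used_aic})
    df = pd.DataFrame(rows)
    df["best"] = df["aicc"] == df["aicc"].min() if len(df) > 1 else False
    return df
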