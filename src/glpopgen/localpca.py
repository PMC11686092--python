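"""Windowed (local) PCA, inter-window distances and MDS for haploblock scans.

Regions of suppressed recombination (inversions, other haploblocks) make the
pattern of genetic covariance among individuals in a window differ from the
genome-wide background.  Each window's individual-by-individual covariance
matrix is normalized to unit trace and reduced to its rank-k approximation;
the dissimilarity between two windows is the Frobenius norm between those
approximations - an efficient simplification of the full Euclidean distance
between covariance structures.  Classical MDS embeds the windows, and
windows whose coordinates sit more than 3 SD from the mean on any retained
axis are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import estimate_maf_em
from .glcore import GLMatrix
from .structure import posterior_mean_genotypes

__all__ = ["WindowEigen", "window_covariances", "window_distance_matrix",
           "classical_mds", "local_pca_scan"]


@dataclass
class WindowEigen:
    chrom: str
    start: int
    end: int
    n_snps: int
    eigenvalues: np.ndarray  # top-k, descending
    approx: np.ndarray  # rank-k approximation of the unit-trace covariance


def _window_bounds_bp(pos: np.ndarray, size: int) -> list[np.ndarray]:
    starts = np.arange(1, pos.max() + 1, size)
    return [
        np.flatnonzero((pos >= s) & (pos <= s + size - 1)) for s in starts
    ]


def _window_bounds_snps(n: int, size: int) -> list[np.ndarray]:
    return [np.arange(i, min(i + size, n)) for i in range(0, n, size)]


def window_covariances(
    gl: GLMatrix,
    k: int = 2,
    window_snps: int | None = 100,
    window_bp: int | None = None,
    min_snps: int | None = None,
) -> list[WindowEigen]:
    """Rank-k covariance summaries of consecutive windows.

    Windows are SNP-count blocks by default (100 SNPs); pass ``window_bp``
    for bp-based windows (e.g. the 1000 bp convention - note that at ~2x
    coverage such windows hold very few SNPs, which is why SNP-count windows
    are the default).  Windows with fewer than ``min_snps`` (default k) SNPs
    are dropped.
    """
    if (window_snps is None) == (window_bp is None):
        raise ValueError("give exactly one of window_snps / window_bp")
    if min_snps is None:
        min_snps = max(k, 2)
    f_all, _ = estimate_maf_em(gl.gls)
    out: list[WindowEigen] = []
    for chrom, grp in gl.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if window_bp is not None:
            blocks = _window_bounds_bp(pos, window_bp)
        else:
            blocks = _window_bounds_snps(len(idx), window_snps)
        for block in blocks:
            if len(block) < min_snps:
                continue
            sel = idx[block]
            f = f_all[sel]
            keep = np.isfinite(f) & (f > 1e-6) & (f < 1 - 1e-6)
            if keep.sum() < min_snps:
                continue
            sel = sel[keep]
            f = f[keep]
            e = posterior_mean_genotypes(gl.gls[sel], f)
            X = (e - 2 * f[:, None]) / np.sqrt(2 * f * (1 - f))[:, None]
            C = X.T @ X / len(sel)
            tr = np.trace(C)
            if tr <= 0:
                continue
            C = C / tr
            lam, vec = np.linalg.eigh(C)
            order = np.argsort(lam)[::-1][:k]
            lam_k, vec_k = lam[order], vec[:, order]
            approx = (vec_k * lam_k) @ vec_k.T
            out.append(
                WindowEigen(str(chrom), int(pos[block[0]]), int(pos[block[-1]]),
                            len(sel), lam_k, approx)
            )
    return out


def window_distance_matrix(windows: list[WindowEigen]) -> np.ndarray:
    """Pairwise Frobenius distances between rank-k covariance approximations."""
    W = len(windows)
    flat = np.stack([w.approx.ravel() for w in windows])
    sq = np.sum(flat**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2 * flat @ flat.T
    return np.sqrt(np.maximum(D2, 0.0))


def classical_mds(D: np.ndarray, dims: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Returns (coordinates (W, dims), eigenvalues).  Axes with non-positive
    eigenvalues come back as zero columns.
    """
    D = np.asarray(D, dtype=float)
    W = D.shape[0]
    J = np.eye(W) - np.ones((W, W)) / W
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    dims = min(dims, W)
    coords = np.zeros((W, dims))
    pos = lam[:dims] > 1e-12
    coords[:, pos] = vec[:, :dims][:, pos] * np.sqrt(lam[:dims][pos])
    return coords, lam


def local_pca_scan(
    gl: GLMatrix,
    k: int = 2,
    mds_dims: int = 10,
    window_snps: int | None = 100,
    window_bp: int | None = None,
    sd_threshold: float = 3.0,
    robust: bool = True,
) -> pd.DataFrame:
    """Windowed PCA + MDS outlier scan.

    Returns a window table (chrom, start, end, n_snps, mds1..mdsK, outlier);
    a window is an outlier if any MDS coordinate deviates more than
    ``sd_threshold`` scale units from that axis's center.  By default the
    center/scale are the median and the MAD (scaled by 1.4826 to be
    SD-consistent): a handful of extreme haploblock windows would otherwise
    inflate a plain standard deviation enough to mask themselves.  Set
    ``robust=False`` for the plain mean/SD rule.
    """
    windows = window_covariances(
        gl, k=k, window_snps=window_snps, window_bp=window_bp
    )
    if len(windows) < 2:
        raise ValueError("need at least two usable windows")
    D = window_distance_matrix(windows)
    coords, _ = classical_mds(D, dims=min(mds_dims, len(windows) - 1))
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
        }
    )
    outlier = np.zeros(len(windows), dtype=bool)
    for j in range(coords.shape[1]):
        col = coords[:, j]
        df[f"mds{j + 1}"] = col
        if robust:
            center = np.median(col)
            scale = 1.4826 * np.median(np.abs(col - center))
            if scale == 0.0:  # degenerate axis: fall back to plain SD
                scale = col.std()
        else:
            center, scale = col.mean(), col.std()
        if scale > 0:
            outlier |= np.abs(col - center) > sd_threshold * scale
    df["outlier"] = outlier
    return df
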