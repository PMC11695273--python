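"""Local-PCA genome scan: windowed PCA, window dissimilarity, MDS, corners.

The genome is cut into consecutive SNP windows per chromosome. Each
window is summarised by the top-k eigenpairs of its sample-covariance
matrix (eigenvalues normalised by the window's total variance). The
dissimilarity between two windows is the Frobenius norm of the
difference of their eigenvalue-weighted rank-k projections, the
dissimilarity matrix is embedded by classical (Torgerson) MDS, and three
extreme "corners" of the embedding are extracted by a deterministic
farthest-point rule. Windows where local relatedness departs from the
genome-wide pattern collect in the corners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .genio import GenotypeMatrix


@dataclass
class WindowSummary:
    eigvals: np.ndarray   # k, normalised by total window variance
    eigvecs: np.ndarray   # n x k
    samples: tuple


@dataclass
class WindowSet:
    windows: pd.DataFrame                       # window_id, chrom, idx ranges, bp span
    summaries: dict = field(default_factory=dict)
    distances: np.ndarray | None = None
    mds: pd.DataFrame | None = None
    corners: pd.Series | None = None


def make_windows(loci: pd.DataFrame, window_snps: int = 25) -> pd.DataFrame:
    """Consecutive blocks of ``window_snps`` SNPs per chromosome.

    A trailing remainder smaller than half a window is merged into the
    previous window; a chromosome with fewer than half a window of SNPs
    becomes a single flagged window. SNP indices refer to row positions
    in ``loci``.
    """
    if not len(loci):
        raise ValueError("empty locus table")
    rows = []
    wid = 0
    for chrom, grp in loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        nsnp = idx.size
        starts = list(range(0, nsnp, window_snps))
        # merge a short trailing remainder into the previous window
        if len(starts) > 1 and nsnp - starts[-1] < window_snps / 2:
            starts = starts[:-1]
        for si, s in enumerate(starts):
            e = starts[si + 1] if si + 1 < len(starts) else nsnp
            block = idx[s:e]
            rows.append({
                "window_id": wid,
                "chrom": chrom,
                "first_snp": int(block[0]),
                "last_snp": int(block[-1]),
                "n_snps": int(block.size),
                "start_bp": int(loci["pos"].iloc[block[0]]),
                "end_bp": int(loci["pos"].iloc[block[-1]]),
                "short": bool(block.size < window_snps / 2),
            })
            wid += 1
    return pd.DataFrame(rows)


def window_pca(G: GenotypeMatrix, snp_index: np.ndarray, k: int = 2) -> WindowSummary:
    """Rank-k eigen summary of one window's sample covariance.

    The window's dosage block is mean-imputed and centred; the
    samples x samples covariance is eigendecomposed and the top-k
    eigenvalues are normalised by the total variance of the window.
    """
    if k >= G.n_samples:
        raise ValueError("k must be smaller than the sample count")
    D = G.dosages[:, snp_index]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(D, axis=0)
    X = np.where(np.isnan(D), mean, D)
    X = X - X.mean(axis=0)
    C = X @ X.T
    total = np.trace(C)
    if total <= 0:
        raise ValueError("monomorphic window")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:k]
    return WindowSummary(eigvals=vals[order] / total, eigvecs=vecs[:, order],
                         samples=tuple(G.samples))


def _projection(w: WindowSummary) -> np.ndarray:
    return (w.eigvecs * w.eigvals) @ w.eigvecs.T


def window_distance(w1: WindowSummary, w2: WindowSummary) -> float:
    """Frobenius distance between eigenvalue-weighted rank-k projections."""
    if w1.samples != w2.samples:
        raise ValueError("windows summarise different sample sets")
    return float(np.linalg.norm(_projection(w1) - _projection(w2)))


def distance_matrix(summaries: list[WindowSummary]) -> np.ndarray:
    """All pairwise window distances (symmetric, zero diagonal)."""
    P = np.stack([_projection(w).ravel() for w in summaries])
    from scipy.spatial.distance import pdist

    return squareform(pdist(P))


def mds_embed(D: np.ndarray, axes: int = 2):
    """Classical (Torgerson) MDS of a dissimilarity matrix.

    Returns (coordinates, eigenvalue fractions). Negative eigenvalues
    (non-Euclidean input) are clamped to zero with a warning.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.size and vals.min() < -1e-8 * max(vals.max(), 1.0):
        warnings.warn("non-Euclidean dissimilarities: negative MDS eigenvalues clamped")
    vals_c = np.clip(vals, 0.0, None)
    coords = vecs[:, :axes] * np.sqrt(vals_c[:axes])
    total = vals_c.sum()
    frac = vals_c[:axes] / total if total > 0 else np.zeros(axes)
    return coords, frac


def extract_corners(coords: np.ndarray, n_corners: int = 3,
                    proportion: float = 0.05) -> tuple[np.ndarray, list[int]]:
    """Deterministic extreme-corner extraction from MDS coordinates.

    Seeds: the window farthest from the centroid; then the window
    farthest from the first seed; then the window maximising the summed
    distance to both. Each corner's set is the ceil(proportion * n)
    windows nearest its seed; contested windows go to the nearest seed
    (ties break toward the lower window index). Returns (assignment
    array with 0 = none, 1..n_corners, seed indices).
    """
    n = coords.shape[0]
    if n < n_corners:
        raise ValueError("fewer windows than corners")
    centroid = coords.mean(axis=0)
    d_cent = np.linalg.norm(coords - centroid, axis=1)
    seeds = [int(np.argmax(d_cent))]
    d1 = np.linalg.norm(coords - coords[seeds[0]], axis=1)
    if n_corners >= 2:
        seeds.append(int(np.argmax(d1)))
    if n_corners >= 3:
        d2 = np.linalg.norm(coords - coords[seeds[1]], axis=1)
        summed = d1 + d2
        summed[seeds] = -np.inf
        seeds.append(int(np.argmax(summed)))
    m = int(np.ceil(proportion * n))
    seed_dists = np.stack([np.linalg.norm(coords - coords[s], axis=1) for s in seeds])
    assign = np.zeros(n, dtype=int)
    claimed: dict[int, int] = {}
    for ci, s in enumerate(seeds):
        nearest = np.argsort(seed_dists[ci], kind="stable")[:m]
        for w in nearest:
            w = int(w)
            if w not in claimed or seed_dists[ci, w] < seed_dists[claimed[w] - 1, w]:
                claimed[w] = ci + 1
    for w, ci in claimed.items():
        assign[w] = ci
    return assign, seeds


def local_pca_scan(G: GenotypeMatrix, loci: pd.DataFrame, window_snps: int = 25,
                   k: int = 2, n_corners: int = 3, proportion: float = 0.05) -> WindowSet:
    """End-to-end local-PCA scan; monomorphic windows are dropped (logged)."""
    wtab = make_windows(loci, window_snps)
    summaries = {}
    for row in wtab.itertuples():
        snps = np.arange(row.first_snp, row.last_snp + 1)
        try:
            summaries[row.window_id] = window_pca(G, snps, k=k)
        except ValueError:
            continue
    usable = [w for w in wtab["window_id"] if w in summaries]
    D = distance_matrix([summaries[w] for w in usable])
    coords, frac = mds_embed(D, axes=2)
    assign, seeds = extract_corners(coords, n_corners=n_corners, proportion=proportion)
    mds = pd.DataFrame(coords, columns=["mds1", "mds2"], index=usable)
    corners = pd.Series(assign, index=usable, name="corner")
    wtab = wtab.set_index("window_id")
    wtab["mds1"] = mds["mds1"]
    wtab["mds2"] = mds["mds2"]
    wtab["corner"] = corners.reindex(wtab.index).fillna(0).astype(int)
    ws = WindowSet(windows=wtab.reset_index(), summaries=summaries,
                   distances=D, mds=mds, corners=corners)
    ws.windows.attrs["mds_eig_fractions"] = list(map(float, frac))
    ws.windows.attrs["corner_seeds"] = [int(usable[s]) for s in seeds]
    return ws
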