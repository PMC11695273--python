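"""Individual ancestry estimation, K selection, and hybrid classification.

Ancestry coefficients are estimated by a sparse nonnegative matrix
factorisation of the dosage matrix: minimise, over the non-missing
entries,

    sum (g_il / 2 - sum_k q_ik f_kl)^2  +  alpha * ||F||^2

subject to q_ik >= 0, sum_k q_ik = 1, 0 <= f_kl <= 1, by alternating
projected least squares (ridge on the ancestral frequencies F, Euclidean
simplex projection on the ancestry rows Q). K is selected by a masked
binomial cross-entropy: a fraction of the observed genotypes is hidden,
the model is refit, and the held-out dosages are scored under
Binomial(2, q_i . f_l).

Individuals are classified as parental when their largest ancestry
coefficient reaches the q-threshold (default 0.80, boundary inclusive),
and as hybrid otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genio import GenotypeMatrix, HYBRID

_EPS = 1e-9


@dataclass
class AncestryConfig:
    K_range: tuple[int, ...] = tuple(range(1, 11))
    repeats: int = 100
    max_iterations: int = 1000
    alpha: float = 100.0
    q_threshold: float = 0.80
    mask_fraction: float = 0.05
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.q_threshold <= 1.0:
            raise ValueError("q_threshold must be in (0.5, 1]")
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must be in (0, 1)")


@dataclass
class AncestryResult:
    Q: pd.DataFrame            # samples x K ancestry coefficients
    F: np.ndarray              # K x SNPs ancestral allele frequencies
    cross_entropy: pd.DataFrame | None
    chosen_K: int
    labels: pd.Series | None = None
    converged: bool = True
    objective: float = field(default=np.nan)


def _project_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    u = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Q - theta[:, None], 0.0)


def _snmf_once(Y, M, K, alpha, max_iter, tol, rng):
    """One alternating projected-least-squares run from a random start.

    The ridge on F is normalised by panel size (effective per-SNP ridge
    alpha * n / L), so the regularisation strength is independent of the
    number of SNPs; the nominal default alpha = 100 is then mild at
    realistic panel sizes instead of overwhelming the per-SNP data terms.
    """
    n, L = Y.shape
    ridge = alpha * n / L
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.1, 0.9, size=(K, L))
    eyeK = np.eye(K)
    MY = M * Y
    prev = np.inf
    for it in range(max_iter):
        # F-step: per-SNP ridge least squares, clipped to [0, 1]
        QQ = Q[:, :, None] * Q[:, None, :]                       # n x K x K
        A = np.einsum("il,ikj->lkj", M, QQ) + ridge * eyeK
        b = MY.T @ Q                                             # L x K
        F = np.clip(np.linalg.solve(A, b[..., None])[..., 0].T, 0.0, 1.0)
        # Q-step: per-sample least squares projected onto the simplex
        FF = F.T[:, :, None] * F.T[:, None, :]                   # L x K x K
        A2 = np.einsum("il,lkj->ikj", M, FF) + 1e-8 * eyeK
        b2 = MY @ F.T                                            # n x K
        Q = _project_simplex(np.linalg.solve(A2, b2[..., None])[..., 0])
        R = M * (Y - Q @ F)
        obj = float(np.sum(R * R) + ridge * np.sum(F * F))
        if prev - obj < tol * max(prev, 1.0):
            return Q, F, obj, True
        prev = obj
    return Q, F, prev, False


def fit_ancestry(G: GenotypeMatrix, K: int, cfg: AncestryConfig,
                 mask: np.ndarray | None = None) -> AncestryResult:
    """Fit Q (samples x K) and F (K x SNPs); best of ``cfg.repeats`` restarts.

    ``mask`` optionally hides extra entries from the fit (used by the
    cross-entropy machinery). K = 1 degenerates to Q = 1 and F = the
    observed allele frequencies (shrunk by the ridge).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    M = (~G.missing).astype(float)
    if mask is not None:
        M = M * (~mask)
    if (M.sum(axis=1) == 0).any():
        raise ValueError("a sample has no observed genotypes")
    Y = np.nan_to_num(G.dosages, nan=0.0) / 2.0
    rng = np.random.default_rng(cfg.seed)
    best = None
    for _ in range(max(cfg.repeats, 1)):
        Q, F, obj, conv = _snmf_once(Y, M, K, cfg.alpha, cfg.max_iterations, cfg.tol, rng)
        if best is None or obj < best[2]:
            best = (Q, F, obj, conv)
    Q, F, obj, conv = best
    Qdf = pd.DataFrame(Q, index=G.samples, columns=[f"q{k + 1}" for k in range(K)])
    return AncestryResult(Q=Qdf, F=F, cross_entropy=None, chosen_K=K,
                          converged=conv, objective=obj)


def cross_entropy(G: GenotypeMatrix, K: int, cfg: AncestryConfig,
                  rng: np.random.Generator | None = None) -> float:
    """Masked binomial cross-entropy for one K.

    Hides ``mask_fraction`` of the non-missing entries (never emptying a
    sample), refits, and returns the negative mean log-probability of the
    held-out dosages under Binomial(2, q_i . f_l).
    """
    rng = np.random.default_rng(cfg.seed + 7919) if rng is None else rng
    observed = ~G.missing
    while True:
        mask = observed & (rng.random(G.dosages.shape) < cfg.mask_fraction)
        if mask.sum() == 0:
            continue
        if not ((observed & ~mask).sum(axis=1) == 0).any():
            break
    res = fit_ancestry(G, K, cfg, mask=mask)
    P = np.clip(res.Q.to_numpy() @ res.F, _EPS, 1.0 - _EPS)
    g = G.dosages[mask]
    p = P[mask]
    return float(-np.mean(binom.logpmf(g.astype(int), 2, p)))


def choose_K(G: GenotypeMatrix, cfg: AncestryConfig,
             improvement_tol: float = 1e-3) -> tuple[int, pd.DataFrame]:
    """Scan ``cfg.K_range``; chosen K minimises the masked cross-entropy.

    A larger K must beat the running best by more than ``improvement_tol``
    to be preferred, so structureless data settle on K = 1.
    """
    rows = []
    best_K, best_ce = None, np.inf
    for K in cfg.K_range:
        ce = cross_entropy(G, K, cfg)
        rows.append((K, ce))
        if ce < best_ce - improvement_tol:
            best_K, best_ce = K, ce
    table = pd.DataFrame(rows, columns=["K", "cross_entropy"])
    return best_K, table


def classify(Q: pd.DataFrame, q_threshold: float = 0.80,
             cluster_names: dict | None = None) -> pd.Series:
    """Two-cluster rule: parental if max q >= threshold, else hybrid."""
    if Q.shape[1] != 2:
        raise ValueError("classification rule is defined for K = 2")
    qmax = Q.to_numpy().max(axis=1)
    which = Q.to_numpy().argmax(axis=1)
    names = cluster_names or {0: "cluster_1", 1: "cluster_2"}
    labels = [names[w] if m >= q_threshold else HYBRID for w, m in zip(which, qmax)]
    return pd.Series(labels, index=Q.index, name="label")


def anchor_clusters(Q: pd.DataFrame, popmap: pd.DataFrame,
                    parental_groups=("parvulus", "pauper")) -> dict:
    """Map cluster column index -> species name by majority vote of prior labels."""
    votes = {}
    which = Q.to_numpy().argmax(axis=1)
    groups = popmap.set_index("sample")["group"]
    for k in range(Q.shape[1]):
        members = groups.reindex(Q.index[which == k])
        counts = members[members.isin(parental_groups)].value_counts()
        votes[k] = counts.idxmax() if len(counts) else f"cluster_{k + 1}"
    if len(set(votes.values())) < len(votes):
        # degenerate vote: fall back to positional names
        votes = {k: f"cluster_{k + 1}" for k in range(Q.shape[1])}
    return votes


def scaled_genotypes(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, centred, sqrt(2p(1-p))-scaled matrix; drops monomorphic SNPs.

    Returns ``(X, kept)`` where ``kept`` indexes the retained SNP columns.
    """
    D = G.dosages
    with np.errstate(invalid="ignore"):
        p = np.nansum(D, axis=0) / (2.0 * np.sum(~np.isnan(D), axis=0))
    kept = np.flatnonzero(~np.isnan(p) & (p > 0) & (p < 1))
    D = D[:, kept]
    p = p[kept]
    X = np.where(np.isnan(D), 2.0 * p, D)
    X = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return X, kept


def pca_embed(G: GenotypeMatrix, n_pcs: int = 2):
    """PCA of the scaled dosage matrix; returns (scores DF, explained fractions)."""
    if G.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    X, _ = scaled_genotypes(G)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(n_pcs, s.size)
    scores = U[:, :n_pcs] * s[:n_pcs]
    frac = (s ** 2) / np.sum(s ** 2)
    df = pd.DataFrame(scores, index=G.samples,
                      columns=[f"PC{i + 1}" for i in range(n_pcs)])
    return df, frac[:n_pcs]
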