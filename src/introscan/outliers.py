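"""Genome scans for divergent selection.

Two scans over the SNP dosage matrix:

* :func:`pcadapt_scan` — principal-component scan. Each SNP is regressed
  on the top-K PC scores; the vector of K z-statistics is summarised by a
  robust Mahalanobis distance D^2, rescaled by the genomic inflation
  factor lambda = median(D^2)/median(chi^2_K), and converted to a
  chi^2_K upper-tail p-value with Bonferroni (family-wise alpha) and
  Benjamini-Hochberg adjustments.

* :func:`outflank_scan` — trimmed chi-square F_ST scan. Uncorrected
  per-SNP F_ST values (weighted among-population variance of allele
  frequency over pbar(1-pbar)) are trimmed at both tails, a scaled
  chi-square null F_ST ~ (Fbar/df) * chi^2_df is fitted to the core by
  truncated maximum likelihood, and right-tail p-values are corrected by
  Benjamini-Hochberg at the requested FDR. Low-heterozygosity SNPs
  (He < he_min) are excluded before fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.covariance import MinCovDet

from .ancestry import scaled_genotypes
from .genio import GenotypeMatrix


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def pcadapt_scan(G: GenotypeMatrix, loci: pd.DataFrame | None = None, K: int = 2,
                 alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """PC-regression Mahalanobis outlier scan.

    Returns a per-SNP table (indexed over the full input SNP set; rows for
    monomorphic SNPs are NaN) with D^2, raw p, Bonferroni and BH adjusted
    p, and outlier flags. Scan metadata (K, lambda, m) lives in ``.attrs``.
    """
    if G.n_samples < K + 2:
        raise ValueError("need at least K + 2 samples")
    X, kept = scaled_genotypes(G)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :K] * s[:K]                       # n x K, orthogonal columns
    n = X.shape[0]
    # per-SNP multiple regression on the PC scores -> K z-statistics
    StS_inv = 1.0 / (s[:K] ** 2)
    beta = (scores.T @ Xc) * StS_inv[:, None]       # K x L
    resid = Xc - scores @ beta
    dof = max(n - K - 1, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (beta / np.sqrt(sigma2[None, :] * StS_inv[:, None])).T  # L x K
    ok = np.isfinite(z).all(axis=1)
    z_ok = z[ok]
    mcd = MinCovDet(random_state=seed).fit(z_ok)
    d2 = mcd.mahalanobis(z_ok)
    lam = float(np.median(d2) / stats.chi2.median(K))
    p = stats.chi2.sf(d2 / lam, K)
    m = p.size
    p_bonf = np.minimum(p * m, 1.0)
    p_bh = _bh_adjust(p)

    L = G.n_snps
    out = pd.DataFrame({
        "stat": np.full(L, np.nan),
        "p": np.full(L, np.nan),
        "p_bonferroni": np.full(L, np.nan),
        "q_bh": np.full(L, np.nan),
        "outlier_bonferroni": np.zeros(L, dtype=bool),
        "outlier_bh": np.zeros(L, dtype=bool),
    })
    rows = kept[ok]
    out.loc[rows, "stat"] = d2
    out.loc[rows, "p"] = p
    out.loc[rows, "p_bonferroni"] = p_bonf
    out.loc[rows, "q_bh"] = p_bh
    out.loc[rows, "outlier_bonferroni"] = p_bonf < alpha
    out.loc[rows, "outlier_bh"] = p_bh < alpha
    if loci is not None:
        out.insert(0, "chrom", loci["chrom"].to_numpy())
        out.insert(1, "pos", loci["pos"].to_numpy())
        out.insert(2, "snp_id", loci["snp_id"].to_numpy())
    out.attrs.update({"K": K, "lambda": lam, "alpha": alpha, "m": int(m)})
    return out


def fst_uncorrected(G: GenotypeMatrix, rows_by_group) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP uncorrected F_ST and expected heterozygosity.

    F_ST = sum_i n_i (p_i - pbar)^2 / ((r-1) nbar) / (pbar (1 - pbar)),
    the Lewontin-Krakauer-type statistic whose null is well approximated
    by a scaled chi-square; no finite-sample correction is applied (the
    fitted null absorbs the offset).
    """
    r = len(rows_by_group)
    n_i, p_i = [], []
    for rows in rows_by_group:
        sub = G.dosages[rows]
        n = np.sum(~np.isnan(sub), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n)
        n_i.append(n)
        p_i.append(p)
    n_i, p_i = np.array(n_i), np.array(p_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = n_i.sum(axis=0)
        nbar = nsum / r
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        he = 2.0 * pbar * (1.0 - pbar)
        fst = s2 / (pbar * (1.0 - pbar))
    bad = np.isnan(pbar) | (pbar <= 0) | (pbar >= 1) | (n_i < 2).any(axis=0)
    fst[bad] = np.nan
    he[np.isnan(pbar)] = np.nan
    return fst, he


def _fit_truncated_chi2(x: np.ndarray, lo: float, hi: float, df0: float, fbar0: float):
    """ML fit of F ~ (Fbar/df) chi^2_df to data truncated to [lo, hi]."""

    def nll(params):
        logdf, logfbar = params
        df, fbar = np.exp(logdf), np.exp(logfbar)
        scale = df / fbar
        z = stats.chi2.cdf(hi * scale, df) - stats.chi2.cdf(lo * scale, df)
        if z <= 0:
            return 1e12
        ll = stats.chi2.logpdf(x * scale, df) + np.log(scale)
        return float(-(ll.sum() - x.size * np.log(z)))

    res = optimize.minimize(nll, x0=[np.log(df0), np.log(fbar0)], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    df, fbar = np.exp(res.x)
    return float(df), float(fbar)


def outflank_scan(G: GenotypeMatrix, popmap: pd.DataFrame, groups,
                  loci: pd.DataFrame | None = None, trim: float = 0.05,
                  he_min: float = 0.10, fdr: float = 0.05) -> pd.DataFrame:
    """Trimmed chi-square F_ST outlier scan.

    Fits the scaled chi-square null to the trimmed core of the F_ST
    distribution (after excluding SNPs with He < ``he_min``) and flags
    right-tail discoveries at BH FDR ``fdr``. Requires >= 50 loci after
    trimming. Fit metadata (df, mean F_ST, trim bounds) in ``.attrs``.
    """
    rows_by_group = [np.flatnonzero((popmap["group"] == g).to_numpy()) for g in groups]
    fst, he = fst_uncorrected(G, rows_by_group)
    usable = np.isfinite(fst) & (he >= he_min)
    x = fst[usable]
    order = np.sort(x)
    k = int(np.floor(trim * order.size))
    core = order[k: order.size - k] if k > 0 else order
    if core.size < 50:
        raise ValueError("fewer than 50 loci after trimming; null fit unstable")
    lo, hi = float(core.min()), float(core.max())
    fbar0 = float(core.mean())
    var0 = float(core.var()) or fbar0 ** 2
    df0 = max(2.0 * fbar0 ** 2 / var0, 0.2)
    df, fbar = _fit_truncated_chi2(core[core > 0], max(lo, 1e-12), hi, df0, fbar0)
    scale = df / fbar
    p = stats.chi2.sf(fst[usable] * scale, df)
    q = _bh_adjust(p)

    L = G.n_snps
    out = pd.DataFrame({
        "fst": fst,
        "he": he,
        "p": np.full(L, np.nan),
        "q_bh": np.full(L, np.nan),
        "outlier": np.zeros(L, dtype=bool),
        "excluded_low_he": ~usable,
    })
    rows = np.flatnonzero(usable)
    out.loc[rows, "p"] = p
    out.loc[rows, "q_bh"] = q
    out.loc[rows, "outlier"] = q < fdr
    if loci is not None:
        out.insert(0, "chrom", loci["chrom"].to_numpy())
        out.insert(1, "pos", loci["pos"].to_numpy())
        out.insert(2, "snp_id", loci["snp_id"].to_numpy())
    out.attrs.update({"df": df, "mean_fst": fbar, "trim": trim, "he_min": he_min,
                      "fdr": fdr, "n_core": int(core.size)})
    return out
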