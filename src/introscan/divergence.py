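"""Divergence and diversity statistics between classified groups.

Implements the Weir & Cockerham (1984) F_ST estimator from its variance
components a (among populations), b (among individuals within
populations) and c (within individuals), the multi-locus ratio-of-sums
theta with a locus-bootstrap confidence interval, per-SNP theta, AMOVA
Phi_ST over RAD-locus haplotypes, and per-group observed/expected
heterozygosity with the inbreeding coefficient F_is = 1 - Ho/He.

Negative per-SNP theta values are retained untruncated: the multi-locus
ratio-of-sums estimate requires raw components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


@dataclass
class FstResult:
    pair: tuple[str, str]
    theta: float
    ci_low: float
    ci_high: float
    components: pd.DataFrame  # per-SNP a, b, c
    n_snps_used: int
    n_snps_skipped: int


def _group_rows(popmap: pd.DataFrame, group: str) -> np.ndarray:
    return np.flatnonzero((popmap["group"] == group).to_numpy())


def wc84_components(G: GenotypeMatrix, rows_by_group: list[np.ndarray]) -> pd.DataFrame:
    """Per-SNP WC84 variance components (a, b, c) for r >= 2 populations.

    Components are computed from per-population sample sizes, allele
    frequencies and observed heterozygote fractions. SNPs where any
    population has fewer than 2 genotyped individuals are emitted as NaN.
    """
    r = len(rows_by_group)
    if r < 2:
        raise ValueError("need at least two groups")
    D = G.dosages
    n_i, p_i, h_i = [], [], []
    for rows in rows_by_group:
        if rows.size < 2:
            raise ValueError("each group needs at least 2 samples")
        sub = D[rows]
        called = ~np.isnan(sub)
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n)
            h = np.nansum(sub == 1, axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # r x L
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nsum = n_i.sum(axis=0)
        nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum

        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (n_i < 2).any(axis=0) | np.isnan(pbar) | (nbar <= 1) | (nc <= 0)
    a[bad] = b[bad] = c[bad] = np.nan
    return pd.DataFrame({"a": a, "b": b, "c": c})


def wc84_theta(G: GenotypeMatrix, popmap: pd.DataFrame, groups: tuple[str, str],
               bootstrap: int = 0, seed: int = 0) -> FstResult:
    """Multi-locus WC84 theta = sum(a) / sum(a + b + c) with optional bootstrap CI."""
    rows = [_group_rows(popmap, g) for g in groups]
    comp = wc84_components(G, rows)
    valid = comp.dropna()
    denom = (valid["a"] + valid["b"] + valid["c"]).to_numpy()
    use = denom != 0
    a = valid["a"].to_numpy()[use]
    d = denom[use]
    theta = float(a.sum() / d.sum())
    ci_low = ci_high = np.nan
    if bootstrap > 0:
        ci_low, ci_high = bootstrap_ci(valid[use], iterations=bootstrap, seed=seed)
    return FstResult(pair=groups, theta=theta, ci_low=ci_low, ci_high=ci_high,
                     components=comp, n_snps_used=int(use.sum()),
                     n_snps_skipped=int(G.n_snps - use.sum()))


def bootstrap_ci(components: pd.DataFrame, iterations: int = 100,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile 95% CI of theta from resampling loci with replacement."""
    comp = components.dropna()
    if len(comp) < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    a = comp["a"].to_numpy()
    d = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    rng = np.random.default_rng(seed)
    L = a.size
    thetas = np.empty(iterations)
    for i in range(iterations):
        idx = rng.integers(0, L, size=L)
        thetas[i] = a[idx].sum() / d[idx].sum()
    return float(np.percentile(thetas, 2.5)), float(np.percentile(thetas, 97.5))


def per_snp_theta(components: pd.DataFrame) -> np.ndarray:
    """Single-locus theta a/(a+b+c); NaN where undefined (monomorphic)."""
    a = components["a"].to_numpy()
    denom = (components["a"] + components["b"] + components["c"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t = a / denom
    t[denom == 0] = np.nan
    return t


def _phase_haplotypes(block: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Expand a (n x S) dosage block into (2n x S) haplotypes, random phase.

    Rows with any missing call yield all-NaN haplotype pairs (dropped by
    the caller).
    """
    n, S = block.shape
    h = np.full((2 * n, S), np.nan)
    for i in range(n):
        row = block[i]
        if np.isnan(row).any():
            continue
        h1 = np.zeros(S)
        h2 = np.zeros(S)
        hom = row == 2
        h1[hom] = h2[hom] = 1
        het = np.flatnonzero(row == 1)
        toss = rng.random(het.size) < 0.5
        h1[het[toss]] = 1
        h2[het[~toss]] = 1
        h[2 * i] = h1
        h[2 * i + 1] = h2
    return h


def amova_phi_st(haplotypes_by_group: list[np.ndarray]) -> float:
    """Phi_ST from an AMOVA on pairwise haplotype difference counts.

    Input: per group, a (haplotypes x sites) 0/1 array. Pairwise distance
    is the count of differing sites, used as the squared molecular
    distance. Returns NaN when the locus is monomorphic overall.
    """
    hs = [h[~np.isnan(h).any(axis=1)] for h in haplotypes_by_group]
    sizes = [len(h) for h in hs]
    if any(s < 2 for s in sizes):
        return np.nan
    allh = np.vstack(hs)
    N, Gn = len(allh), len(hs)
    if np.all(allh == allh[0]):
        return np.nan

    def ssd(h):
        # sum of pairwise difference counts / group size
        m = h @ h.T
        ones = h.sum(axis=1)
        d = ones[:, None] + ones[None, :] - 2 * m
        return d[np.triu_indices(len(h), k=1)].sum() / len(h)

    ssd_total = ssd(allh)
    ssd_within = sum(ssd(h) for h in hs)
    ssd_among = ssd_total - ssd_within
    df_among = Gn - 1
    df_within = N - Gn
    ms_within = ssd_within / df_within
    n_prime = (N - sum(s * s for s in sizes) / N) / df_among
    sigma_a = (ssd_among / df_among - ms_within) / n_prime
    total = sigma_a + ms_within
    if total == 0:
        return np.nan
    return float(sigma_a / total)


def per_snp_divergence(G: GenotypeMatrix, loci: pd.DataFrame, popmap: pd.DataFrame,
                       groups: tuple[str, str], seed: int = 0) -> pd.DataFrame:
    """Per-SNP WC84 theta plus per-RAD-locus AMOVA Phi_ST.

    Haplotypes are the concatenated SNP alleles of each RAD locus;
    heterozygous sites are expanded by random phase under ``seed``.
    Phi_ST is repeated on every SNP row of its locus.
    """
    rows = [_group_rows(popmap, g) for g in groups]
    comp = wc84_components(G, rows)
    theta = per_snp_theta(comp)
    rng = np.random.default_rng(seed)
    phi = np.full(G.n_snps, np.nan)
    for _, idx in loci.groupby("radlocus_id", sort=False).groups.items():
        cols = np.asarray(idx)
        haps = [_phase_haplotypes(G.dosages[np.ix_(r, cols)], rng) for r in rows]
        phi[cols] = amova_phi_st(haps)
    return pd.DataFrame(
        {
            "chrom": loci["chrom"].to_numpy(),
            "pos": loci["pos"].to_numpy(),
            "snp_id": loci["snp_id"].to_numpy(),
            "theta": theta,
            "phi_st": phi,
        }
    )


def het_stats(G: GenotypeMatrix, rows: np.ndarray) -> dict:
    """Per-group mean observed/expected heterozygosity and F_is.

    Per SNP: Ho = heterozygote fraction; He = 2p(1-p) * 2n/(2n-1)
    (unbiased). Group values are means over polymorphic SNPs;
    F_is = 1 - mean(Ho)/mean(He), NaN when He is 0 everywhere.
    """
    sub = G.dosages[rows]
    called = ~np.isnan(sub)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(sub, axis=0) / (2.0 * n)
        ho = np.nansum(sub == 1, axis=0) / n
        he = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
    poly = ~np.isnan(p) & (p > 0) & (p < 1) & (n >= 2)
    if not poly.any():
        return {"Ho": 0.0, "He": 0.0, "Fis": np.nan, "n_individuals": int(rows.size)}
    Ho = float(ho[poly].mean())
    He = float(he[poly].mean())
    return {
        "Ho": Ho,
        "He": He,
        "Fis": 1.0 - Ho / He if He > 0 else np.nan,
        "n_individuals": int(rows.size),
    }


def diversity_table(G: GenotypeMatrix, popmap: pd.DataFrame, groups) -> pd.DataFrame:
    """Group summary table: N, Ho, He, F_is (private-allele counts join later)."""
    rows = []
    for g in groups:
        stats = het_stats(G, _group_rows(popmap, g))
        rows.append({"group": g, **stats})
    return pd.DataFrame(rows)
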