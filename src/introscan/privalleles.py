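"""Private-allele identification and introgression tracking.

A private allele is an allele observed (frequency > 0) in exactly one of
the two parental populations and absent (observed frequency exactly 0)
in the other. Privacy is defined on the parental samples only; hybrid
genotypes never veto it. For every private allele the hybrid frequency is
computed overall and per sampling year, the high-frequency rule
(hybrid frequency >= 0.30, boundary inclusive) is applied, frequency
shifts between years are classified, and a subsampling procedure
measures the sensitivity of all of it to hybrid sample size.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HYBRID, PARVULUS, PAUPER

RECORD_COLUMNS = [
    "snp", "snp_id", "chrom", "pos", "allele", "origin",
    "freq_origin", "freq_other", "freq_hybrid_all",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (matches hand-reported percentages)."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


def _freqs(D: np.ndarray, rows: np.ndarray) -> np.ndarray:
    sub = D[rows]
    with np.errstate(invalid="ignore"):
        return np.nansum(sub, axis=0) / (2.0 * np.sum(~np.isnan(sub), axis=0))


def find_private_alleles(
    G: GenotypeMatrix,
    loci: pd.DataFrame,
    popmap: pd.DataFrame,
    parental_groups: tuple[str, str] = (PARVULUS, PAUPER),
    hybrid_group: str = HYBRID,
    threshold: float = 0.30,
    low_support_n: int = 3,
) -> pd.DataFrame:
    """Enumerate parental private alleles with hybrid frequencies per year.

    Returns one row per (SNP, allele) private to one parental group, with
    the origin frequency, the hybrid frequency overall and per year, the
    cross-year delta (later minus earlier, when two years exist), and the
    flags: ``high_freq`` (hybrid frequency >= threshold),
    ``exceeds_origin`` (strict), ``present_both_years`` (observed > 0 in
    hybrids in both years) and ``low_support`` (any year with fewer than
    ``low_support_n`` genotyped hybrids). SNPs with no genotyped parental
    individual in either group are skipped (counted in ``.attrs``).
    """
    D = G.dosages
    grp = popmap["group"].to_numpy()
    year = popmap["year"].to_numpy()
    rows_par = {g: np.flatnonzero(grp == g) for g in parental_groups}
    for g, r in rows_par.items():
        if r.size == 0:
            raise ValueError(f"parental group {g!r} is empty")
    rows_hyb = np.flatnonzero(grp == hybrid_group)
    years = sorted(pd.unique(pd.Series(year[rows_hyb]).dropna()))

    f_par = {g: _freqs(D, r) for g, r in rows_par.items()}
    f_hyb = _freqs(D, rows_hyb) if rows_hyb.size else np.full(G.n_snps, np.nan)
    f_hyb_year = {}
    n_hyb_year = {}
    for y in years:
        r = rows_hyb[year[rows_hyb] == y]
        f_hyb_year[y] = _freqs(D, r)
        n_hyb_year[y] = np.sum(~np.isnan(D[r]), axis=0)

    g1, g2 = parental_groups
    skipped = int((np.isnan(f_par[g1]) | np.isnan(f_par[g2])).sum())
    records = []
    for origin, other in ((g1, g2), (g2, g1)):
        fo, fx = f_par[origin], f_par[other]
        ok = ~np.isnan(fo) & ~np.isnan(fx)
        for allele, fo_a, fx_a in (("alt", fo, fx), ("ref", 1.0 - fo, 1.0 - fx)):
            hyb_a = f_hyb if allele == "alt" else 1.0 - f_hyb
            private = ok & (fo_a > 0) & (fx_a == 0)
            for snp in np.flatnonzero(private):
                rec = {
                    "snp": int(snp),
                    "snp_id": loci["snp_id"].iat[snp],
                    "chrom": loci["chrom"].iat[snp],
                    "pos": int(loci["pos"].iat[snp]),
                    "allele": allele,
                    "origin": origin,
                    "freq_origin": float(fo_a[snp]),
                    "freq_other": 0.0,
                    "freq_hybrid_all": float(hyb_a[snp]) if not np.isnan(hyb_a[snp]) else np.nan,
                }
                low_support = False
                for y in years:
                    fy = f_hyb_year[y][snp]
                    fy_a = fy if allele == "alt" else 1.0 - fy
                    rec[f"freq_hybrid_{y}"] = float(fy_a) if not np.isnan(fy) else np.nan
                    if n_hyb_year[y][snp] < low_support_n:
                        low_support = True
                rec["low_support"] = low_support
                records.append(rec)
    out = pd.DataFrame(records)
    if out.empty:
        out = pd.DataFrame(columns=RECORD_COLUMNS + ["low_support"])
    out.attrs["years"] = [str(y) for y in years]
    out.attrs["n_snps_skipped"] = skipped
    if len(years) >= 2:
        y1, y2 = years[0], years[-1]
        f1 = out.get(f"freq_hybrid_{y1}", pd.Series(dtype=float))
        f2 = out.get(f"freq_hybrid_{y2}", pd.Series(dtype=float))
        out["delta"] = f2 - f1
        out["present_both_years"] = (f1 > 0) & (f2 > 0)
    out = high_freq_subset(out, threshold)
    if "freq_hybrid_all" in out and len(out):
        out["exceeds_origin"] = out["freq_hybrid_all"] > out["freq_origin"]
    else:
        out["exceeds_origin"] = pd.Series(dtype=bool)
    return out


def high_freq_subset(records: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Flag records whose overall hybrid frequency reaches the threshold."""
    records = records.copy()
    if len(records):
        records["high_freq"] = records["freq_hybrid_all"] >= threshold
    else:
        records["high_freq"] = pd.Series(dtype=bool)
    records.attrs.update(getattr(records, "attrs", {}))
    return records


def origin_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Per-origin counts of alleles exceeding their origin frequency.

    Ties never count as exceeding. Emitted per origin species, both over
    all private alleles and restricted to the high-frequency subset;
    percentages are rounded half-up to the nearest integer.
    """
    rows = []
    for subset_name, sub in (("all", records),
                             ("high_freq", records[records.get("high_freq", False) == True] if len(records) else records)):
        for origin, grp in (sub.groupby("origin") if len(sub) else []):
            n = len(grp)
            n_exceeds = int((grp["freq_hybrid_all"] > grp["freq_origin"]).sum())
            rows.append({
                "subset": subset_name,
                "origin": origin,
                "n_private": n,
                "n_exceeds_origin": n_exceeds,
                "fraction_exceeds": n_exceeds / n if n else np.nan,
                "percent_exceeds": round_half_up(100.0 * n_exceeds / n) if n else np.nan,
            })
    return pd.DataFrame(rows, columns=["subset", "origin", "n_private",
                                       "n_exceeds_origin", "fraction_exceeds",
                                       "percent_exceeds"])


def year_shift(records: pd.DataFrame, delta_threshold: float = 0.30) -> pd.DataFrame:
    """Classify cross-year frequency shifts per origin species.

    Restricted to alleles observed in hybrids in both years
    (``present_both_years``). Classes: increase (delta > 0), decrease
    (delta < 0), unchanged (delta == 0). Reports counts, the count with
    |delta| >= ``delta_threshold``, and mean |delta| with its standard
    error per class per origin.
    """
    if "present_both_years" not in records.columns:
        raise ValueError("records lack per-year hybrid frequencies (need two sampling years)")
    both = records[records["present_both_years"].fillna(False)]
    rows = []
    for origin, grp in (both.groupby("origin") if len(both) else []):
        d = grp["delta"].to_numpy()
        for cls, mask in (("increase", d > 0), ("decrease", d < 0), ("unchanged", d == 0)):
            sel = np.abs(d[mask])
            rows.append({
                "origin": origin,
                "class": cls,
                "n": int(mask.sum()),
                "n_large_shift": int((sel >= delta_threshold).sum()),
                "mean_abs_delta": float(sel.mean()) if sel.size else np.nan,
                "se_abs_delta": float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else np.nan,
                "n_present_both": len(grp),
            })
    return pd.DataFrame(rows, columns=["origin", "class", "n", "n_large_shift",
                                       "mean_abs_delta", "se_abs_delta", "n_present_both"])


def _summary_numbers(records: pd.DataFrame) -> dict:
    """Flat numeric summary used by the subsampling report."""
    out = {}
    comp = origin_comparison(records)
    for _, r in comp.iterrows():
        key = f"{r['subset']}_{r['origin']}"
        out[f"n_private_{key}"] = float(r["n_private"])
        out[f"n_exceeds_{key}"] = float(r["n_exceeds_origin"])
    out["n_private_total"] = float(len(records))
    out["n_high_freq"] = float(records["high_freq"].sum()) if len(records) else 0.0
    if "present_both_years" in records.columns:
        shifts = year_shift(records)
        for _, r in shifts.iterrows():
            key = f"{r['origin']}_{r['class']}"
            out[f"n_shift_{key}"] = float(r["n"])
            out[f"n_large_shift_{key}"] = float(r["n_large_shift"])
    return out


def subsample_sensitivity(
    G: GenotypeMatrix,
    loci: pd.DataFrame,
    popmap: pd.DataFrame,
    n_target: int,
    year,
    replicates: int = 3,
    seed: int = 0,
    threshold: float = 0.30,
    hybrid_group: str = HYBRID,
) -> dict:
    """Redo the private-allele chain with hybrids of ``year`` subsampled.

    Per replicate, ``n_target`` hybrids of the given year are drawn
    without replacement (all other samples kept), the full chain
    (find -> high-freq -> origin comparison -> year shifts) is recomputed,
    and the numeric summaries are averaged across replicates.
    Returns ``{"replicates": [...], "mean": {...}, "identity": bool}``.
    """
    rng = np.random.default_rng(seed)
    is_target = ((popmap["group"] == hybrid_group) & (popmap["year"].astype(str) == str(year))).to_numpy()
    pool = np.flatnonzero(is_target)
    if pool.size == 0:
        raise ValueError(f"no genotyped hybrids in year {year!r}")
    identity = n_target >= pool.size
    reps = []
    for _ in range(replicates):
        if identity:
            keep_rows = np.arange(G.n_samples)
        else:
            chosen = rng.choice(pool, size=n_target, replace=False)
            drop = np.setdiff1d(pool, chosen)
            keep_rows = np.setdiff1d(np.arange(G.n_samples), drop)
        Gs = G.take_samples(keep_rows)
        pms = popmap.iloc[keep_rows].reset_index(drop=True)
        recs = find_private_alleles(Gs, loci, pms, threshold=threshold,
                                    hybrid_group=hybrid_group)
        reps.append(_summary_numbers(recs))
    keys = sorted(set().union(*[r.keys() for r in reps]))
    mean = {k: float(np.mean([r.get(k, 0.0) for r in reps])) for k in keys}
    return {"replicates": reps, "mean": mean, "identity": identity}


def records_to_bed(records: pd.DataFrame) -> pd.DataFrame:
    """BED-style track (0-based half-open) of private-allele positions."""
    if not len(records):
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return pd.DataFrame({
        "chrom": records["chrom"],
        "start": records["pos"] - 1,
        "end": records["pos"],
        "name": records["origin"] + ":" + records["allele"],
    })
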