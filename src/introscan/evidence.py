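"""Combined-evidence candidate tables and reclassification summaries.

Joins the three lines of evidence for selection on introgressed
variation — high-frequency private alleles, PC-scan outliers, and
local-PCA corner windows — into a tiered candidate table, and computes
the cross-tabulation of prior (microsatellite-era) group labels against
the SNP-based classification together with the percentage summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .privalleles import round_half_up


def combine_evidence(records: pd.DataFrame, outlier_table: pd.DataFrame,
                     windows: pd.DataFrame) -> pd.DataFrame:
    """Tiered candidate table from high-frequency private alleles.

    Candidates are the private-allele records with ``high_freq`` set.
    ``in_outlier`` marks records whose (chrom, pos) is a flagged scan
    outlier; ``in_corner_window`` marks positions inside a corner
    window's bp span. Tier = 1 (high_freq) + in_outlier + in_corner.
    Sorted by tier then |delta| descending.
    """
    cand = records[records["high_freq"]].copy() if len(records) else records.copy()
    if not len(cand):
        cols = list(records.columns) + ["in_outlier", "in_corner_window", "corner_window_id", "tier"]
        return pd.DataFrame(columns=cols)
    if cand.duplicated(["chrom", "pos", "allele"]).any():
        raise ValueError("duplicated (chrom, pos, allele) candidates; coordinate mismatch")

    flag_col = "outlier_bonferroni" if "outlier_bonferroni" in outlier_table.columns else "outlier"
    hits = outlier_table[outlier_table[flag_col].fillna(False).astype(bool)]
    hit_pos = set(zip(hits["chrom"], hits["pos"]))
    cand["in_outlier"] = [
        (c, p) in hit_pos for c, p in zip(cand["chrom"], cand["pos"])
    ]

    corner_win = windows[windows["corner"] > 0]
    win_id = []
    in_win = []
    for c, p in zip(cand["chrom"], cand["pos"]):
        match = corner_win[(corner_win["chrom"] == c)
                           & (corner_win["start_bp"] <= p)
                           & (corner_win["end_bp"] >= p)]
        if len(match):
            in_win.append(True)
            win_id.append(int(match["window_id"].iloc[0]))
        else:
            in_win.append(False)
            win_id.append(-1)
    cand["in_corner_window"] = in_win
    cand["corner_window_id"] = win_id
    cand["tier"] = 1 + cand["in_outlier"].astype(int) + cand["in_corner_window"].astype(int)
    if "delta" in cand.columns:
        cand = cand.sort_values(["tier", "delta"], key=lambda s: s.abs() if s.name == "delta" else s,
                                ascending=[False, False], kind="mergesort")
    else:
        cand = cand.sort_values("tier", ascending=False, kind="mergesort")
    return cand.reset_index(drop=True)


def reclassification_summary(prior: pd.Series, new: pd.Series):
    """Cross-tabulate prior vs new labels; percentages per prior group.

    Returns ``(counts, percents)`` where each percentage is
    100 * cell / row-total rounded half-up to the nearest integer.
    """
    if set(prior.index) != set(new.index):
        raise ValueError("prior and new labels cover different samples")
    new = new.reindex(prior.index)
    counts = pd.crosstab(prior, new, dropna=False)
    counts.index.name = "prior"
    counts.columns.name = "new"
    totals = counts.sum(axis=1)
    percents = counts.apply(
        lambda col: [round_half_up(100.0 * v / t) if t else np.nan
                     for v, t in zip(col, totals)]
    )
    return counts, percents


def per_year_hybrid_counts(popmap: pd.DataFrame, prior: pd.Series, new: pd.Series,
                           hybrid_label: str = "hybrid") -> pd.DataFrame:
    """Hybrid counts per sampling year under both labelings."""
    years = popmap.set_index("sample")["year"]
    rows = []
    for year in sorted(years.dropna().unique(), key=str):
        samples = years[years == year].index
        rows.append({
            "year": year,
            "n_prior_hybrid": int((prior.reindex(samples) == hybrid_label).sum()),
            "n_new_hybrid": int((new.reindex(samples) == hybrid_label).sum()),
        })
    return pd.DataFrame(rows)


def percent_change(before: int, after: int) -> float:
    """Signed percentage change, rounded half-up to one decimal."""
    if before <= 0:
        raise ValueError("percent change undefined for before <= 0")
    raw = 100.0 * (after - before) / before
    sign = -1.0 if raw < 0 else 1.0
    return sign * round_half_up(abs(raw), 1)
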