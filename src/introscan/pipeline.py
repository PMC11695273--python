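"""End-to-end pipeline orchestration.

Stage order mirrors the study's two-pass design: stage-1 SNP filter
under the prior (field/microsatellite) group labels, neutral-structure
analysis and hybrid re-classification, stage-2 re-filter under the
SNP-based labels, then divergence statistics, private-allele tracking,
outlier scans, local PCA and the combined-evidence report. Every stage
writes tab-separated artifacts plus a manifest of seeds and input hashes
so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, divergence, evidence, genio, kinship, localpca, outliers, privalleles


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    outdir: str
    seed: int = None  # type: ignore[assignment]  # must be given explicitly
    maf_min: float = 0.03
    call_rate_min: float = 0.75
    q_threshold: float = 0.80
    k_range: tuple[int, ...] = (1, 2, 3)
    snmf_repeats: int = 10
    snmf_alpha: float = 100.0
    bootstrap: int = 100
    private_threshold: float = 0.30
    subsample_n: int | None = None
    subsample_year: str | None = None
    subsample_replicates: int = 3
    scan_k: int = 2
    scan_alpha: float = 0.05
    outflank_trim: float = 0.05
    outflank_he_min: float = 0.10
    outflank_fdr: float = 0.05
    window_snps: int = 25
    window_pcs: int = 2
    n_corners: int = 3
    corner_proportion: float = 0.05
    parental_groups: tuple[str, str] = (genio.PARVULUS, genio.PAUPER)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("pipeline config requires an explicit seed")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory results and writes artifacts."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "inputs": {"vcf": _sha256(cfg.vcf), "popmap": _sha256(cfg.popmap)},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stages": {},
    }
    results: dict = {}

    # stage 1: read + filter under prior labels
    G, loci, popmap = genio.read_vcf(cfg.vcf, cfg.popmap)
    fcfg = genio.FilterConfig(maf_min=cfg.maf_min, call_rate_min=cfg.call_rate_min)
    G1, loci1, rep1 = genio.filter_snps(G, loci, popmap, fcfg)
    G1t, loci1t = genio.thin_one_snp_per_locus(G1, loci1)
    manifest["stages"]["filter_stage1"] = {"n_input": rep1.n_input, "n_kept": rep1.n_kept,
                                           "n_thinned": G1t.n_snps}
    genio.individual_missingness(G1).to_csv(out / "missingness.tsv", sep="\t")

    # relatedness screen
    kin = kinship.king_kinship(G1t)
    kin.to_frame().to_csv(out / "kinship.tsv", sep="\t", index=False)
    results["kinship"] = kin

    # ancestry + classification on the thinned stage-1 set
    acfg = ancestry.AncestryConfig(K_range=tuple(cfg.k_range), repeats=cfg.snmf_repeats,
                                   alpha=cfg.snmf_alpha, q_threshold=cfg.q_threshold,
                                   seed=cfg.seed)
    chosen_K, ce_table = ancestry.choose_K(G1t, acfg)
    fit = ancestry.fit_ancestry(G1t, 2, acfg)
    names = ancestry.anchor_clusters(fit.Q, popmap, cfg.parental_groups)
    labels = ancestry.classify(fit.Q, cfg.q_threshold, cluster_names=names)
    ce_table.to_csv(out / "cross_entropy.tsv", sep="\t", index=False)
    fit.Q.assign(label=labels).to_csv(out / "qmatrix.tsv", sep="\t")
    pcs, explained = ancestry.pca_embed(G1t, 2)
    pcs.to_csv(out / "pca.tsv", sep="\t")
    manifest["stages"]["ancestry"] = {"chosen_K": int(chosen_K),
                                      "n_hybrid": int((labels == genio.HYBRID).sum())}
    results.update({"chosen_K": chosen_K, "cross_entropy": ce_table, "Q": fit.Q,
                    "labels": labels, "pca": pcs})

    # stage 2: re-filter under the SNP-based labels
    popmap2 = popmap.copy()
    popmap2["group"] = labels.reindex(popmap2["sample"]).to_numpy()
    G2, loci2, rep2 = genio.filter_snps(G, loci, popmap2, fcfg)
    manifest["stages"]["filter_stage2"] = {"n_kept": rep2.n_kept}
    results.update({"G2": G2, "loci2": loci2, "popmap2": popmap2})

    # divergence between classified groups
    gpair = cfg.parental_groups
    fst_rows = []
    pairs = [gpair, (gpair[0], genio.HYBRID), (gpair[1], genio.HYBRID)]
    for pair in pairs:
        if all((popmap2["group"] == g).sum() >= 2 for g in pair):
            r = divergence.wc84_theta(G2, popmap2, pair, bootstrap=cfg.bootstrap, seed=cfg.seed)
            fst_rows.append({"group_1": pair[0], "group_2": pair[1], "theta": r.theta,
                             "ci_low": r.ci_low, "ci_high": r.ci_high, "n_snps": r.n_snps_used})
    fst_table = pd.DataFrame(fst_rows)
    fst_table.to_csv(out / "fst.tsv", sep="\t", index=False)
    div = divergence.diversity_table(G2, popmap2, list(gpair) + [genio.HYBRID])
    per_snp = divergence.per_snp_divergence(G2, loci2, popmap2, gpair, seed=cfg.seed)
    per_snp.to_csv(out / "per_snp_divergence.tsv", sep="\t", index=False)
    results.update({"fst": fst_table, "diversity": div})

    # private alleles + year shifts + subsampling
    records = privalleles.find_private_alleles(G2, loci2, popmap2,
                                               parental_groups=gpair,
                                               threshold=cfg.private_threshold)
    records.to_csv(out / "private_alleles.tsv", sep="\t", index=False)
    comparison = privalleles.origin_comparison(records)
    comparison.to_csv(out / "private_origin_comparison.tsv", sep="\t", index=False)
    div = div.merge(
        records.groupby("origin").size().rename("n_private").reset_index(),
        how="left", left_on="group", right_on="origin",
    ).drop(columns="origin")
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    shifts = None
    if "present_both_years" in records.columns:
        shifts = privalleles.year_shift(records)
        shifts.to_csv(out / "private_year_shifts.tsv", sep="\t", index=False)
    subsample = None
    if cfg.subsample_n and cfg.subsample_year is not None:
        subsample = privalleles.subsample_sensitivity(
            G2, loci2, popmap2, cfg.subsample_n, cfg.subsample_year,
            replicates=cfg.subsample_replicates, seed=cfg.seed,
            threshold=cfg.private_threshold)
        (out / "private_subsample.json").write_text(json.dumps(subsample, indent=2))
    results.update({"private_records": records, "origin_comparison": comparison,
                    "year_shifts": shifts, "subsample": subsample})

    # outlier scans
    scan_pc = outliers.pcadapt_scan(G2, loci2, K=cfg.scan_k, alpha=cfg.scan_alpha,
                                    seed=cfg.seed)
    scan_pc.to_csv(out / "scan_pcadapt.tsv", sep="\t", index=False)
    scan_of = None
    try:
        scan_of = outliers.outflank_scan(G2, popmap2, gpair, loci2,
                                         trim=cfg.outflank_trim,
                                         he_min=cfg.outflank_he_min,
                                         fdr=cfg.outflank_fdr)
        scan_of.to_csv(out / "scan_outflank.tsv", sep="\t", index=False)
    except ValueError:
        pass
    results.update({"scan_pcadapt": scan_pc, "scan_outflank": scan_of})

    # local PCA
    ws = localpca.local_pca_scan(G2, loci2, window_snps=cfg.window_snps,
                                 k=cfg.window_pcs, n_corners=cfg.n_corners,
                                 proportion=cfg.corner_proportion)
    ws.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    results["windows"] = ws

    # combined evidence + reclassification
    ev = evidence.combine_evidence(records, scan_pc, ws.windows)
    ev.to_csv(out / "evidence.tsv", sep="\t", index=False)
    prior = popmap.set_index("sample")["group"]
    counts, percents = evidence.reclassification_summary(prior, labels)
    counts.to_csv(out / "reclassification_counts.tsv", sep="\t")
    percents.to_csv(out / "reclassification_percents.tsv", sep="\t")
    results.update({"evidence": ev, "reclass_counts": counts, "reclass_percents": percents})
    manifest["stages"]["evidence"] = {"n_candidates": int(len(ev)),
                                      "n_tier2_plus": int((ev["tier"] >= 2).sum()) if len(ev) else 0}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
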