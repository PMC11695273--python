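"""Synthetic two-species hybrid-swarm SNP datasets with known truth.

Emulates the sampling design of a two-species tree-finch hybrid swarm:
two parental populations diverged to a target multi-locus F_ST under the
Balding-Nichols model, F1 hybrids and parvulus-directed backcrosses, SNPs
grouped into multi-SNP RAD loci laid out over many chromosomes, two
sampling years separated by one round of Wright-Fisher drift, and uniform
random genotype missingness.

The generator records a :class:`TruthSet` (true ancestry fractions,
parental-exclusive alleles, planted divergent loci) so every downstream
stage of the pipeline can be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HYBRID, LOCUS_COLUMNS, PARVULUS, PAUPER, write_popmap, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class YearCohort:
    """Per-year sample counts for each group."""

    label: str
    n_parvulus: int = 0
    n_pauper: int = 0
    n_f1: int = 0
    n_backcross: int = 0


@dataclass
class SimConfig:
    n_loci: int = 10_000
    n_chromosomes: int = 30
    snps_per_radlocus: int = 1
    target_fst: float = 0.035
    n_parvulus: int = 50
    n_pauper: int = 30
    n_f1: int = 5
    n_backcross: int = 10
    backcross_generations: int = 1
    years: list[YearCohort] | None = None
    drift_ne: int = 500
    missing_rate: float = 0.0
    planted_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_loci,
            self.n_chromosomes,
            self.snps_per_radlocus,
            self.n_parvulus,
            self.n_pauper,
            self.n_f1,
            self.n_backcross,
            self.planted_outliers,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.backcross_generations < 1:
            raise ValueError("backcross_generations must be >= 1")
        if self.cohorts() and sum(
            c.n_parvulus + c.n_pauper + c.n_f1 + c.n_backcross for c in self.cohorts()
        ) == 0:
            raise ValueError("all sample counts are zero")

    def cohorts(self) -> list[YearCohort]:
        """Per-year cohorts; a single unnamed year when ``years`` is None."""
        if self.years is not None:
            return list(self.years)
        return [
            YearCohort("1", self.n_parvulus, self.n_pauper, self.n_f1, self.n_backcross)
        ]

    @property
    def n_snps(self) -> int:
        return self.n_loci * self.snps_per_radlocus


@dataclass
class TruthSet:
    """Ground truth recorded by the generator."""

    ancestry_true: pd.Series  # per-sample true parvulus ancestry fraction
    private_true: pd.DataFrame  # columns: snp, allele, origin
    outlier_true: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def simulate_parental_freqs(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw per-SNP parental allele-frequency pairs under Balding-Nichols.

    The ancestral frequency ``p`` is uniform on [0.05, 0.95]; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``target_fst``. F = 0 degenerates to both populations at exactly
    ``p``. The first ``planted_outliers`` RAD loci are overridden to fixed
    differences (parvulus 1, pauper 0 at every SNP of the locus).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m = cfg.n_snps
    p = rng.uniform(0.05, 0.95, size=m)
    F = cfg.target_fst
    if F == 0.0:
        f_parv, f_paup = p.copy(), p.copy()
    else:
        a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
        f_parv = rng.beta(a, b)
        f_paup = rng.beta(a, b)
    if cfg.planted_outliers:
        if cfg.planted_outliers > cfg.n_loci:
            raise ValueError("planted_outliers exceeds n_loci")
        planted = np.arange(cfg.planted_outliers * cfg.snps_per_radlocus)
        f_parv[planted] = 1.0
        f_paup[planted] = 0.0
    return f_parv, f_paup


def _make_locus_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out snps_per_radlocus consecutive SNPs per RAD locus across chromosomes."""
    n_chr = max(cfg.n_chromosomes, 1)
    locus_chrom = np.arange(cfg.n_loci) % n_chr
    rows = []
    pos_counter = np.zeros(n_chr, dtype=int)
    for loc in range(cfg.n_loci):
        c = locus_chrom[loc]
        start = pos_counter[c] + 1000  # RAD loci spaced 1 kb apart
        for s in range(cfg.snps_per_radlocus):
            snp = loc * cfg.snps_per_radlocus + s
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                (f"snp_{snp}", f"rad_{loc}", f"chr{c + 1}", start + s * 10,
                 _BASES[ref], _BASES[alt])
            )
        pos_counter[c] = start + cfg.snps_per_radlocus * 10
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    key = loci["chrom"].str.removeprefix("chr").astype(int)
    loci = loci.assign(_k=key).sort_values(["_k", "pos"], kind="mergesort").drop(columns="_k")
    return loci.reset_index(drop=True)


def _draw_haplotypes(freqs_by_locus, origins, rng):
    """Draw one haplotype per RAD locus given per-locus parental origins.

    ``freqs_by_locus``: (2, n_loci, snps_per_locus) parental frequencies;
    ``origins``: (n_loci,) 0=parvulus, 1=pauper. All SNPs of one RAD locus
    descend from the same parental haplotype (tight linkage).
    """
    f = freqs_by_locus[origins, np.arange(origins.size)]
    return (rng.random(f.shape) < f).astype(np.int8)


def simulate_genotypes(freqs, cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the full sample set; returns (GenotypeMatrix, loci, popmap, TruthSet).

    Parental individuals draw both haplotypes from their own population;
    an F1 draws one from each; a generation-g backcross toward parvulus
    draws one haplotype from parvulus and the other from parvulus with
    probability 1 - 2^(-g), giving expected ancestry 1 - 2^(-g-1).
    Second-year frequencies undergo one binomial Wright-Fisher round of
    size 2*drift_ne before that year's individuals are sampled.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    f_parv, f_paup = freqs
    cohorts = cfg.cohorts()
    if sum(c.n_parvulus + c.n_pauper + c.n_f1 + c.n_backcross for c in cohorts) == 0:
        raise ValueError("all sample counts are zero")
    loci = _make_locus_table(cfg, rng)
    # reorder frequencies to match the sorted locus table
    snp_order = loci["snp_id"].str.removeprefix("snp_").astype(int).to_numpy()
    f_parv = np.asarray(f_parv, dtype=float)[snp_order]
    f_paup = np.asarray(f_paup, dtype=float)[snp_order]
    locus_of_snp = loci["radlocus_id"].str.removeprefix("rad_").astype(int).to_numpy()
    # group SNP columns by RAD locus for linked haplotype draws
    by_locus = np.argsort(locus_of_snp, kind="mergesort").reshape(cfg.n_loci, cfg.snps_per_radlocus)

    samples, groups, years, ancestry = [], [], [], []
    dosage_rows = []
    counter = {"parvulus": 0, "pauper": 0, "F1": 0, "BC": 0}

    def freq_stack(fp, fq):
        stack = np.empty((2, cfg.n_loci, cfg.snps_per_radlocus))
        stack[0] = fp[by_locus]
        stack[1] = fq[by_locus]
        return stack

    for cohort_i, cohort in enumerate(cohorts):
        if cohort_i == 0:
            fp, fq = f_parv, f_paup
        else:
            # one Wright-Fisher binomial round per population between years
            fp = rng.binomial(2 * cfg.drift_ne, f_parv) / (2 * cfg.drift_ne)
            fq = rng.binomial(2 * cfg.drift_ne, f_paup) / (2 * cfg.drift_ne)
        fs = freq_stack(fp, fq)
        plan = (
            [("parvulus", 0.0, None)] * cohort.n_parvulus
            + [("pauper", 1.0, None)] * cohort.n_pauper
            + [("F1", None, 0)] * cohort.n_f1
            + [("BC", None, None)] * cohort.n_backcross
        )
        for kind, _, _ in plan:
            counter[kind] += 1
            if kind == "parvulus":
                o1 = o2 = np.zeros(cfg.n_loci, dtype=int)
                a_true, group = 1.0, PARVULUS
            elif kind == "pauper":
                o1 = o2 = np.ones(cfg.n_loci, dtype=int)
                a_true, group = 0.0, PAUPER
            elif kind == "F1":
                o1 = np.zeros(cfg.n_loci, dtype=int)
                o2 = np.ones(cfg.n_loci, dtype=int)
                a_true, group = 0.5, HYBRID
            else:  # backcross toward parvulus, generation cycling 1..G
                g = (counter["BC"] - 1) % cfg.backcross_generations + 1
                o1 = np.zeros(cfg.n_loci, dtype=int)
                o2 = (rng.random(cfg.n_loci) < 2.0 ** (-g)).astype(int)
                a_true, group = 1.0 - 2.0 ** (-g - 1), HYBRID
            h1 = _draw_haplotypes(fs, o1, rng)
            h2 = _draw_haplotypes(fs, o2, rng)
            dos = np.empty(cfg.n_snps, dtype=float)
            dos[by_locus.ravel()] = (h1 + h2).ravel()
            dosage_rows.append(dos)
            name = f"{kind}_{counter[kind]}"
            samples.append(name)
            groups.append(group)
            years.append(cohort.label)
            # true ancestry toward parvulus: note pauper haplotypes count 0
            ancestry.append(a_true)

    D = np.array(dosage_rows)
    if cfg.missing_rate > 0:
        D[rng.random(D.shape) < cfg.missing_rate] = np.nan
    G = GenotypeMatrix(samples, D)
    popmap = pd.DataFrame({"sample": samples, "group": groups, "year": years})

    truth = TruthSet(
        ancestry_true=pd.Series(ancestry, index=samples, name="ancestry_parvulus"),
        private_true=_observed_private(G, popmap),
        outlier_true=np.flatnonzero(
            loci["radlocus_id"].isin([f"rad_{i}" for i in range(cfg.planted_outliers)])
        ),
    )
    return G, loci, popmap, truth


def _observed_private(G: GenotypeMatrix, popmap: pd.DataFrame) -> pd.DataFrame:
    """Alleles observed in exactly one parental sample (truth bookkeeping)."""
    rows = []
    idx = {g: np.flatnonzero((popmap["group"] == g).to_numpy()) for g in (PARVULUS, PAUPER)}
    if idx[PARVULUS].size == 0 or idx[PAUPER].size == 0:
        return pd.DataFrame(columns=["snp", "allele", "origin"])
    from .genio import alt_freq

    f = {g: alt_freq(G, idx[g]) for g in (PARVULUS, PAUPER)}
    for origin, other in ((PARVULUS, PAUPER), (PAUPER, PARVULUS)):
        fo, fx = f[origin], f[other]
        ok = ~np.isnan(fo) & ~np.isnan(fx)
        for snp in np.flatnonzero(ok & (fo > 0) & (fx == 0)):
            rows.append((int(snp), "alt", origin))
        for snp in np.flatnonzero(ok & (fo < 1) & (fx == 1)):
            rows.append((int(snp), "ref", origin))
    return pd.DataFrame(rows, columns=["snp", "allele", "origin"])


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: frequencies + genotypes in one call."""
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_parental_freqs(cfg, rng)
    return simulate_genotypes(freqs, cfg, rng)


def write_dataset(G: GenotypeMatrix, loci: pd.DataFrame, popmap: pd.DataFrame, outdir) -> dict:
    """Write the simulated dataset as VCF + population map; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "genotypes.vcf"
    pop_path = outdir / "popmap.tsv"
    write_vcf(G, loci, vcf_path)
    write_popmap(popmap, pop_path)
    return {"vcf": vcf_path, "popmap": pop_path}
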