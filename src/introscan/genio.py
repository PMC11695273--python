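"""Genotype I/O and SNP filtering.

Reads biallelic-SNP VCFs plus a tab-separated population map into the
pipeline's in-memory model (dosage matrix + locus table + popmap) and
applies the RADseq-style SNP filters: overall minor-allele-frequency
cutoff, per-population call-rate cutoff, and one-SNP-per-RAD-locus
thinning.

Conventions
-----------
* Dosage is the count of ALT alleles per diploid genotype: 0, 1, 2;
  missing calls are ``NaN`` in the float matrix.
* Coordinates are 1-based inclusive (VCF convention); chromosome names
  are carried verbatim.
* Missing genotypes are excluded from every frequency denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # cyvcf2 is the reader; the writer below is plain text
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover
    _CyVCF = None

logger = logging.getLogger(__name__)

LOCUS_COLUMNS = ["snp_id", "radlocus_id", "chrom", "pos", "ref", "alt"]

PARVULUS = "parvulus"
PAUPER = "pauper"
HYBRID = "hybrid"
UNKNOWN = "unknown"


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix with NaN for missing calls."""

    samples: list[str]
    dosages: np.ndarray  # float, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count does not match dosage rows")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing genotype calls."""
        return np.isnan(self.dosages)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix([self.samples[i] for i in idx], self.dosages[idx])

    def take_snps(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.dosages[:, idx])


def alt_freq(G: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Per-SNP ALT allele frequency over non-missing genotypes.

    Returns NaN where no genotype is observed.
    """
    D = G.dosages if rows is None else G.dosages[rows]
    with np.errstate(invalid="ignore"):
        return np.nansum(D, axis=0) / (2.0 * np.sum(~np.isnan(D), axis=0))


@dataclass
class FilterConfig:
    """SNP filter settings: overall MAF floor and per-population call rate."""

    maf_min: float = 0.03
    call_rate_min: float = 0.75
    per_population: bool = True
    one_snp_per_locus: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 < self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in (0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_kept: int
    per_population_groups: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "maf", "call_rate", "kept"],
                "n": [self.n_input, self.n_removed_maf, self.n_removed_callrate, self.n_kept],
            }
        )


def read_popmap(path) -> pd.DataFrame:
    """Read a ``sample<TAB>group<TAB>year`` population map."""
    pm = pd.read_csv(
        path, sep="\t", header=None, names=["sample", "group", "year"], dtype={"sample": str, "group": str}
    )
    if pm["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in population map")
    return pm


def write_popmap(popmap: pd.DataFrame, path) -> None:
    popmap[["sample", "group", "year"]].to_csv(path, sep="\t", header=False, index=False)


def read_vcf(path, popmap_path=None):
    """Read a biallelic-SNP VCF (and optional popmap) into the data model.

    Returns ``(GenotypeMatrix, LocusTable, PopMap)``. Multi-allelic or
    non-SNP records are skipped (count logged). Samples without a popmap
    entry are labelled ``unknown``.
    """
    if _CyVCF is None:  # pragma: no cover
        raise RuntimeError("cyvcf2 is required to read VCF files")
    vcf = _CyVCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        dosage_cols.append(dos)
        rad = var.INFO.get("RAD")
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append(
            (snp_id, rad if rad is not None else snp_id, var.CHROM, var.POS, var.REF, var.ALT[0])
        )
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    if loci.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chromosome, position) records in VCF")
    G = GenotypeMatrix(samples, np.column_stack(dosage_cols))

    if popmap_path is None:
        popmap = pd.DataFrame({"sample": samples, "group": UNKNOWN, "year": pd.NA})
    else:
        pm = read_popmap(popmap_path)
        if not set(samples) & set(pm["sample"]):
            raise ValueError("no overlap between VCF samples and population map")
        pm = pm.set_index("sample")
        popmap = pd.DataFrame(
            {
                "sample": samples,
                "group": [pm["group"].get(s, UNKNOWN) for s in samples],
                "year": [pm["year"].get(s, pd.NA) for s in samples],
            }
        )
    return G, loci, popmap


def write_vcf(G: GenotypeMatrix, loci: pd.DataFrame, path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT and RAD locus INFO tags."""
    if len(loci) != G.n_snps:
        raise ValueError("locus table does not match genotype matrix width")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RAD,Number=1,Type=String,Description="RAD locus id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        D = G.dosages
        for j, row in enumerate(loci.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(D[i, j]) else gt_map[D[i, j]] for i in range(G.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"RAD={row.radlocus_id}\tGT\t{gts}\n"
            )


def filter_snps(G: GenotypeMatrix, loci: pd.DataFrame, popmap: pd.DataFrame, cfg: FilterConfig):
    """Apply the MAF and per-population call-rate filters.

    A SNP is kept iff (i) its overall minor allele frequency over
    non-missing genotypes is >= ``maf_min`` and (ii) its call rate is
    >= ``call_rate_min`` within every population defined by the popmap's
    group labels at call time.
    """
    groups = list(pd.unique(popmap["group"]))
    for g in groups:
        if (popmap["group"] == g).sum() == 0:  # pragma: no cover - defensive
            raise ValueError(f"population {g!r} has zero samples")
    f = alt_freq(G)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(f, 1.0 - f)
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= cfg.maf_min

    keep_cr = np.ones(G.n_snps, dtype=bool)
    if cfg.per_population:
        called = ~G.missing
        for g in groups:
            rows = np.flatnonzero((popmap["group"] == g).to_numpy())
            if rows.size == 0:
                raise ValueError(f"population {g!r} has zero samples")
            rate = called[rows].mean(axis=0)
            keep_cr &= rate >= cfg.call_rate_min
    else:
        rate = (~G.missing).mean(axis=0)
        keep_cr = rate >= cfg.call_rate_min

    keep = keep_maf & keep_cr
    report = FilterReport(
        n_input=G.n_snps,
        n_removed_maf=int((~keep_maf).sum()),
        n_removed_callrate=int((keep_maf & ~keep_cr).sum()),
        n_kept=int(keep.sum()),
        per_population_groups=groups if cfg.per_population else [],
    )
    Gf = G.take_snps(keep)
    locif = loci.loc[keep].reset_index(drop=True)
    if cfg.one_snp_per_locus:
        Gf, locif = thin_one_snp_per_locus(Gf, locif)
    return Gf, locif, report


def thin_one_snp_per_locus(G: GenotypeMatrix, loci: pd.DataFrame):
    """Retain one SNP per RAD locus: the first by position."""
    order = loci.sort_values(["radlocus_id", "pos"], kind="mergesort")
    first = order.drop_duplicates("radlocus_id", keep="first").index
    keep = np.sort(first.to_numpy())
    return G.take_snps(keep), loci.loc[keep].reset_index(drop=True)


def individual_missingness(G: GenotypeMatrix) -> pd.Series:
    """Fraction of missing SNP calls per sample."""
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    return pd.Series(G.missing.mean(axis=1), index=G.samples, name="missingness")
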